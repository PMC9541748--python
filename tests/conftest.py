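import dataclasses

import pandas as pd
import pytest

from ricurve import ingest, synthetic


@pytest.fixture
def toy_csv(tmp_path):
    """Small valid breeding-record CSV covering all exclusion classes."""

    def make(rows, name="records.csv", columns=None):
        path = tmp_path / name
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
        return path

    return make


def record(**kw):
    base = dict(
        individual_id="a", population="P", sex="female", birth_year=2000,
        breed_year=2001, age=1, clutch_size=7, clutch_type="first",
        polygamous=False,
    )
    base.update(kw)
    return ingest.BreedingRecord(**base)


@pytest.fixture
def make_record():
    return record


@pytest.fixture
def quiet_config():
    """A noise-free single population for controlled-injection tests."""
    return synthetic.PopulationConfig(
        "quiet", annual_survival=0.5, base_clutch=8.0,
        year_effect_sd=0.0, quality_sd=0.0, noise_sd=0.0,
    )


@pytest.fixture
def noiseless_presets():
    """Fast/slow presets with every stochastic nuisance switched off."""
    strip = lambda c: dataclasses.replace(  # noqa: E731
        c, year_effect_sd=0.0, quality_sd=0.0, noise_sd=0.0
    )
    return strip(synthetic.FAST_PRESET), strip(synthetic.SLOW_PRESET)


def run_series_pipeline(records_df: pd.DataFrame, min_length: int = 3):
    """records frame -> centred IndividualSeries list + FilterReport (in memory)."""
    records = [
        ingest.BreedingRecord(**{k: r[k] for k in ingest.DEFAULT_SCHEMA})
        for r in records_df.to_dict("records")
    ]
    firsts, report = ingest.apply_exclusions(records)
    means = ingest.compute_population_year_means(firsts)
    series, report = ingest.build_continuous_series(firsts, min_length=min_length, report=report)
    series = [ingest.centre_series(s, means) for s in series]
    return series, report
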