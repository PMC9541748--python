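"""End-to-end orchestration: simulate/ingest -> decompose -> classify -> fit -> report.

Every stage writes plain CSV/JSON artifacts into the run directory and
consumes only the previous stage's files, so a run can be resumed from any
intermediate.  A manifest records the effective configuration and a SHA-256
hash of every artifact; identical configuration + seed must produce
identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import fourier, inference, ingest, synthetic

__all__ = ["RunConfig", "EmptyCohortError", "run_pipeline",
           "stage_simulate", "stage_ingest", "stage_decompose",
           "stage_classify", "stage_fit", "write_manifest"]

MEASURES = ("absolute", "centred")
RESPONSES = ("timescale_binary", "amplitude_short", "amplitude_long")


class EmptyCohortError(ValueError):
    """No individual survived the ingest filters."""


@dataclass
class RunConfig:
    outdir: str
    input_path: str | None = None
    simulate: dict | None = None  # {"n_individuals": int, "populations": [...]} or {}
    measure: str = "both"  # absolute | centred | both
    cutoff_mode: str = "inclusive_at_2"  # or below_4
    retain_threshold: float = 2.0
    averaging: str = "conditional"
    seed: int = 0
    round_clutches: bool = True
    schema: dict | None = None
    min_length: int = 3
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path / simulate must be given")
        if self.retain_threshold <= 0:
            raise ValueError("retain_threshold must be > 0")
        if self.measure not in ("absolute", "centred", "both"):
            raise ValueError(f"unknown measure {self.measure!r}")
        if self.cutoff_mode not in ("inclusive_at_2", "below_4"):
            raise ValueError(f"unknown cutoff_mode {self.cutoff_mode!r}")

    @property
    def measures(self) -> tuple[str, ...]:
        return MEASURES if self.measure == "both" else (self.measure,)

    @staticmethod
    def from_yaml(path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _configs_from_spec(spec: dict) -> list[synthetic.PopulationConfig]:
    pops = spec.get("populations")
    if not pops:
        return synthetic.default_study_configs()
    return [synthetic.PopulationConfig(**p) for p in pops]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    spec = config.simulate or {}
    configs = _configs_from_spec(spec)
    records, truth = synthetic.simulate_study(
        configs,
        n_individuals=int(spec.get("n_individuals", 200)),
        seed=config.seed,
        round_clutches=config.round_clutches,
    )
    rec_path = outdir / "records.csv"
    truth_path = outdir / "truth.csv"
    echo_path = outdir / "simulate_config.yaml"
    records.to_csv(rec_path, index=False)
    truth.to_csv(truth_path, index=False)
    echo_path.write_text(yaml.safe_dump(
        {"seed": config.seed, "round_clutches": config.round_clutches,
         "n_individuals": int(spec.get("n_individuals", 200)),
         "populations": [dataclasses.asdict(c) for c in configs]},
        sort_keys=True))
    return [rec_path, truth_path, echo_path]


def stage_ingest(config: RunConfig, outdir: Path) -> list[Path]:
    source = config.input_path if config.input_path else outdir / "records.csv"
    records = ingest.parse_records(source, schema=config.schema)
    firsts, report = ingest.apply_exclusions(records)
    means = ingest.compute_population_year_means(firsts)
    series_list, report = ingest.build_continuous_series(
        firsts, min_length=config.min_length, report=report
    )
    if not series_list:
        report.to_json(outdir / "filter_report.json")
        raise EmptyCohortError("no individuals survived filtering; see filter_report.json")
    series_list = [ingest.centre_series(s, means) for s in series_list]

    series_path = outdir / "series.csv"
    report_path = outdir / "filter_report.json"
    means_path = outdir / "population_year_means.csv"
    ingest.series_to_frame(series_list).to_csv(series_path, index=False)
    report.to_json(report_path)
    pd.DataFrame([m.__dict__ for m in means]).to_csv(means_path, index=False)
    return [series_path, report_path, means_path]


def _load_series(outdir: Path):
    return ingest.frame_to_series(pd.read_csv(outdir / "series.csv"))


def _series_values(series, measure: str):
    return series.clutch_values if measure == "absolute" else series.centred_values


def stage_decompose(config: RunConfig, outdir: Path) -> list[Path]:
    series_list = _load_series(outdir)
    decomps = []
    for measure in config.measures:
        for s in series_list:
            decomps.append(
                fourier.decompose(_series_values(s, measure), s.individual_id, measure)
            )
    path = outdir / "modes.csv"
    fourier.modes_to_frame(decomps).to_csv(path, index=False)
    return [path]


def stage_classify(config: RunConfig, outdir: Path) -> list[Path]:
    series_list = _load_series(outdir)
    pops = {s.individual_id: s.population for s in series_list}
    cls_all = []
    summaries = {}
    for measure in config.measures:
        cls = []
        for s in series_list:
            decomp = fourier.decompose(_series_values(s, measure), s.individual_id, measure)
            if decomp.n_present_modes == 0:
                continue  # constant series: no strategy to classify
            cls.append(fourier.classify(decomp, cutoff_mode=config.cutoff_mode))
        cls_all.extend(cls)
        summaries[measure] = fourier.cohort_summary(cls, populations=pops)
    cls_path = outdir / "classifications.csv"
    sum_path = outdir / "cohort_summary.json"
    fourier.classifications_to_frame(cls_all).to_csv(cls_path, index=False)
    sum_path.write_text(json.dumps(summaries, indent=2, sort_keys=True))
    return [cls_path, sum_path]


def stage_fit(config: RunConfig, outdir: Path) -> list[Path]:
    series_list = _load_series(outdir)
    by_id = {s.individual_id: s for s in series_list}
    cls_df = pd.read_csv(outdir / "classifications.csv")
    paths: list[Path] = []
    emm_rows = []
    avg_rows = []
    meta = {"seed": config.seed, "retain_threshold": config.retain_threshold,
            "averaging": config.averaging,
            "reference_levels": dict(inference.DEFAULT_REFERENCE_LEVELS),
            "dropped_zero_amplitude": {}, "n_obs": {}}
    for measure in config.measures:
        sub = cls_df[cls_df["measure"] == measure]
        cls = [_row_to_classification(r) for r in sub.itertuples(index=False)]
        table = inference.build_analysis_table(
            [by_id[c.individual_id] for c in cls], cls
        )
        for response in RESPONSES:
            data = table.dropna(subset=[inference._RESPONSE_COLUMNS[response]])
            candidates = inference.enumerate_candidates(response, measure)
            transform = candidates[0].transform
            if transform == "log":
                col = inference._RESPONSE_COLUMNS[response]
                n_zero = int((data[col] <= 0).sum())
                meta["dropped_zero_amplitude"][f"{response}/{measure}"] = n_zero
                data = data[data[col] > 0]
            if len(data) < 12:
                continue  # too few rows to fit the full candidate set
            fits = [inference.fit_model(m, data) for m in candidates]
            sel = inference.select_models(fits, retain_threshold=config.retain_threshold)
            sel_path = outdir / f"selection_{response}_{measure}.csv"
            sel.to_frame().to_csv(sel_path, index=False)
            paths.append(sel_path)
            meta["n_obs"][f"{response}/{measure}"] = int(len(data))

            averaged, _retained = inference.average_within_delta(sel, method=config.averaging)
            for name, value in averaged.items():
                avg_rows.append({"response": response, "measure": measure,
                                 "term": name, "estimate": value})
            for factor in ("population", "sex"):
                emm = inference.marginal_means(sel.best_fit, data, factor)
                emm.insert(0, "measure", measure)
                emm.insert(0, "response", response)
                emm_rows.append(emm)

    avg_path = outdir / "averaged_coefficients.csv"
    emm_path = outdir / "emm.csv"
    meta_path = outdir / "fit_metadata.json"
    pd.DataFrame(avg_rows).to_csv(avg_path, index=False)
    (pd.concat(emm_rows, ignore_index=True) if emm_rows else pd.DataFrame()).to_csv(
        emm_path, index=False)
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return paths + [avg_path, emm_path, meta_path]


def _row_to_classification(row) -> fourier.RICClassification:
    sec_wl = getattr(row, "secondary_wavelength")
    absent = sec_wl is None or (isinstance(sec_wl, float) and np.isnan(sec_wl))
    return fourier.RICClassification(
        individual_id=str(row.individual_id),
        measure=str(row.measure),
        dominant_wavelength=float(row.dominant_wavelength),
        dominant_amplitude=float(row.dominant_amplitude),
        secondary_wavelength=None if absent else float(sec_wl),
        secondary_amplitude=None if absent else float(row.secondary_amplitude),
        dominant_scale=str(row.dominant_scale),
        secondary_scale=None if absent else str(row.secondary_scale),
        has_short_and_long=bool(row.has_short_and_long),
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def write_manifest(outdir: Path, config: RunConfig, artifacts: list[Path],
                   status: dict[str, str]) -> Path:
    manifest = {
        "config": dataclasses.asdict(config),
        "stages": status,
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts)) if p.exists()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order; returns the manifest path.

    On stage failure, the manifest is still written with the failed stage
    marked, then the error propagates.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stages = []
    if config.simulate is not None:
        stages.append(("simulate", stage_simulate))
    stages += [("ingest", stage_ingest), ("decompose", stage_decompose),
               ("classify", stage_classify), ("fit", stage_fit)]

    artifacts: list[Path] = []
    status: dict[str, str] = {}
    for name, fn in stages:
        try:
            artifacts.extend(fn(config, outdir))
            status[name] = "ok"
        except Exception as exc:
            status[name] = f"failed: {exc}"
            write_manifest(outdir, config, artifacts, status)
            raise
    return write_manifest(outdir, config, artifacts, status)
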