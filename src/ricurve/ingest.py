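"""Read, filter and assemble longitudinal breeding records.

Input is a long-format table of nest-box breeding attempts (one row per
individual x breeding year).  Records are filtered down to first clutches of
monogamous pairs, assembled into gap-free per-individual clutch-size time
series of at least three breeding attempts, and expressed on two scales:

* **absolute clutch size** — the raw egg count, and
* **mean-centred clutch size** — the deviation from the population-year
  average clutch, which removes shared inter-annual environmental variation.

The lifetime mean clutch of each individual is kept as a quality covariate
for the downstream models.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BreedingRecord",
    "FilterReport",
    "IndividualSeries",
    "PopulationYearMean",
    "SchemaError",
    "ParseError",
    "DataIntegrityError",
    "MissingMeanError",
    "EmptySeriesError",
    "DEFAULT_SCHEMA",
    "parse_records",
    "apply_exclusions",
    "build_continuous_series",
    "compute_population_year_means",
    "centre_series",
    "mean_individual_clutch",
    "series_to_frame",
    "frame_to_series",
    "records_to_frame",
]

#: canonical field -> expected CSV column name; remap by passing a copy with
#: the values changed.
DEFAULT_SCHEMA: dict[str, str] = {
    "individual_id": "individual_id",
    "population": "population",
    "sex": "sex",
    "birth_year": "birth_year",
    "breed_year": "breed_year",
    "age": "age",
    "clutch_size": "clutch_size",
    "clutch_type": "clutch_type",
    "polygamous": "polygamous",
}

VALID_SEX = frozenset({"female", "male"})
VALID_CLUTCH_TYPE = frozenset({"first", "second", "replacement"})
_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class ParseError(ValueError):
    """A cell could not be coerced to its declared type."""


class DataIntegrityError(ValueError):
    """Duplicate (individual, year) rows after restriction to first clutches."""


class MissingMeanError(KeyError):
    """No population-year mean is available for a (population, year) pair."""


class EmptySeriesError(ValueError):
    """An operation was asked for on a series with no observations."""


@dataclass(frozen=True)
class BreedingRecord:
    """One observed breeding attempt."""

    individual_id: str
    population: str
    sex: str
    birth_year: int
    breed_year: int
    age: int
    clutch_size: int
    clutch_type: str = "first"
    polygamous: bool = False


@dataclass
class FilterReport:
    """Counts of what each exclusion rule removed."""

    n_input: int = 0
    n_excluded_second: int = 0
    n_excluded_replacement: int = 0
    n_excluded_polygamous: int = 0
    n_individuals_dropped_gap: int = 0
    n_individuals_dropped_short: int = 0
    per_population_n: dict[str, int] = field(default_factory=dict)

    @property
    def n_retained_records(self) -> int:
        return (
            self.n_input
            - self.n_excluded_second
            - self.n_excluded_replacement
            - self.n_excluded_polygamous
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


@dataclass(frozen=True)
class IndividualSeries:
    """A gap-free per-individual clutch-size time series (length >= 3).

    ``centred_values`` is ``None`` until :func:`centre_series` has run.
    """

    individual_id: str
    population: str
    sex: str
    birth_year: int
    first_breed_year: int
    ages: tuple[int, ...]
    clutch_values: tuple[int, ...]
    centred_values: tuple[float, ...] | None
    mean_individual_clutch: float

    def __len__(self) -> int:
        return len(self.clutch_values)

    @property
    def breed_years(self) -> tuple[int, ...]:
        return tuple(self.first_breed_year + j for j in range(len(self)))


@dataclass(frozen=True)
class PopulationYearMean:
    population: str
    breed_year: int
    mean_clutch: float
    n_records: int


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _coerce_int(value, what: str, row: int) -> int:
    try:
        out = int(str(value).strip())
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: cannot parse {what} value {value!r} as an integer") from None
    return out


def _coerce_clutch(value, row: int) -> float:
    """Clutch sizes are egg counts, but the simulator's no-rounding
    diagnostic mode produces real values; accept any numeric, keep integers
    as integers."""
    try:
        out = float(str(value).strip())
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: cannot parse clutch_size value {value!r} as a number") from None
    return int(out) if float(out).is_integer() else out


def _coerce_bool(value, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ParseError(f"row {row}: cannot parse polygamous value {value!r} as a boolean")


def parse_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[BreedingRecord]:
    """Read breeding records from a CSV file, preserving row order.

    ``schema`` maps canonical field names to the CSV's column names; fields
    absent from the mapping fall back to :data:`DEFAULT_SCHEMA`.
    """
    columns = dict(DEFAULT_SCHEMA)
    if schema:
        columns.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [col for col in columns.values() if col not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")

    records: list[BreedingRecord] = []
    for row_idx, row in enumerate(df.itertuples(index=False), start=1):
        get = lambda f: getattr(row, columns[f])  # noqa: E731
        sex = str(get("sex")).strip().lower()
        if sex not in VALID_SEX:
            raise ParseError(f"row {row_idx}: invalid sex {sex!r} (expected female/male)")
        ctype = str(get("clutch_type")).strip().lower()
        if ctype not in VALID_CLUTCH_TYPE:
            raise ParseError(
                f"row {row_idx}: invalid clutch_type {ctype!r} "
                f"(expected first/second/replacement)"
            )
        rec = BreedingRecord(
            individual_id=str(get("individual_id")).strip(),
            population=str(get("population")).strip(),
            sex=sex,
            birth_year=_coerce_int(get("birth_year"), "birth_year", row_idx),
            breed_year=_coerce_int(get("breed_year"), "breed_year", row_idx),
            age=_coerce_int(get("age"), "age", row_idx),
            clutch_size=_coerce_clutch(get("clutch_size"), row_idx),
            clutch_type=ctype,
            polygamous=_coerce_bool(get("polygamous"), row_idx),
        )
        if rec.clutch_size < 0:
            raise ParseError(f"row {row_idx}: clutch_size must be >= 0")
        if rec.age < 1:
            raise ParseError(f"row {row_idx}: age must be >= 1")
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Record-level exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(
    records: Sequence[BreedingRecord],
    report: FilterReport | None = None,
) -> tuple[list[BreedingRecord], FilterReport]:
    """Keep only first clutches of non-polygamous pairs.

    Second and replacement clutches reflect a different investment decision
    than a single first clutch, and polygamous pairings confound per-parent
    investment, so all three classes are removed outright.
    """
    rep = report if report is not None else FilterReport()
    rep.n_input += len(records)
    retained: list[BreedingRecord] = []
    for rec in records:
        if rec.clutch_type == "second":
            rep.n_excluded_second += 1
        elif rec.clutch_type == "replacement":
            rep.n_excluded_replacement += 1
        elif rec.polygamous:
            rep.n_excluded_polygamous += 1
        else:
            retained.append(rec)
    return retained, rep


# ---------------------------------------------------------------------------
# Series assembly
# ---------------------------------------------------------------------------

def build_continuous_series(
    records: Sequence[BreedingRecord],
    min_length: int = 3,
    report: FilterReport | None = None,
) -> tuple[list[IndividualSeries], FilterReport]:
    """Assemble gap-free per-individual series, dropping broken ones.

    An individual with any interior gap in its breeding years is dropped
    entirely (we cannot tell a skipped breeding attempt from breeding outside
    the study area); series shorter than ``min_length`` carry no oscillatory
    signal and are dropped too.  Terminal truncation (death or emigration)
    never causes exclusion.
    """
    rep = report if report is not None else FilterReport()
    by_individual: dict[str, list[BreedingRecord]] = defaultdict(list)
    for rec in records:
        by_individual[rec.individual_id].append(rec)

    series_list: list[IndividualSeries] = []
    for ind_id, recs in by_individual.items():
        recs = sorted(recs, key=lambda r: r.breed_year)
        years = [r.breed_year for r in recs]
        if len(set(years)) != len(years):
            dup = next(y for y in years if years.count(y) > 1)
            raise DataIntegrityError(
                f"individual {ind_id!r} has duplicate first-clutch records in year {dup}"
            )
        if any(b - a > 1 for a, b in zip(years, years[1:])):
            rep.n_individuals_dropped_gap += 1
            continue
        if len(recs) < min_length:
            rep.n_individuals_dropped_short += 1
            continue
        clutches = tuple(r.clutch_size for r in recs)
        series = IndividualSeries(
            individual_id=ind_id,
            population=recs[0].population,
            sex=recs[0].sex,
            birth_year=recs[0].birth_year,
            first_breed_year=years[0],
            ages=tuple(r.age for r in recs),
            clutch_values=clutches,
            centred_values=None,
            mean_individual_clutch=float(np.mean(clutches)),
        )
        series_list.append(series)
        rep.per_population_n[series.population] = (
            rep.per_population_n.get(series.population, 0) + 1
        )
    return series_list, rep


# ---------------------------------------------------------------------------
# Centring
# ---------------------------------------------------------------------------

def compute_population_year_means(
    records: Sequence[BreedingRecord],
) -> list[PopulationYearMean]:
    """Mean first clutch per (population, breeding year).

    Computed from *all* first-clutch records — including individuals later
    dropped for gaps or short series — so the environmental average reflects
    the full population sample.
    """
    sums: dict[tuple[str, int], list[float]] = defaultdict(list)
    for rec in records:
        sums[(rec.population, rec.breed_year)].append(rec.clutch_size)
    return [
        PopulationYearMean(pop, year, float(np.mean(vals)), len(vals))
        for (pop, year), vals in sorted(sums.items())
    ]


def _mean_lookup(means: Iterable[PopulationYearMean]) -> dict[tuple[str, int], float]:
    return {(m.population, m.breed_year): m.mean_clutch for m in means}


def centre_series(
    series: IndividualSeries,
    means: Sequence[PopulationYearMean] | Mapping[tuple[str, int], float],
) -> IndividualSeries:
    """Populate ``centred_values`` = clutch − population-year mean."""
    lookup = means if isinstance(means, Mapping) else _mean_lookup(means)
    centred = []
    for year, clutch in zip(series.breed_years, series.clutch_values):
        key = (series.population, year)
        if key not in lookup:
            raise MissingMeanError(
                f"no population-year mean for population {series.population!r}, year {year}"
            )
        centred.append(float(clutch) - lookup[key])
    return replace(series, centred_values=tuple(centred))


def mean_individual_clutch(series: IndividualSeries) -> float:
    """Lifetime mean absolute clutch size (the quality covariate)."""
    if len(series) == 0:
        raise EmptySeriesError("cannot take the mean clutch of an empty series")
    return float(np.mean(series.clutch_values))


# ---------------------------------------------------------------------------
# Frame round-trips (pipeline persistence)
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[BreedingRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def series_to_frame(series_list: Sequence[IndividualSeries]) -> pd.DataFrame:
    """Long format, one row per individual-year, centred value appended."""
    rows = []
    for s in series_list:
        centred = s.centred_values if s.centred_values is not None else [np.nan] * len(s)
        for year, age, clutch, cen in zip(s.breed_years, s.ages, s.clutch_values, centred):
            rows.append(
                {
                    "individual_id": s.individual_id,
                    "population": s.population,
                    "sex": s.sex,
                    "birth_year": s.birth_year,
                    "breed_year": year,
                    "age": age,
                    "clutch_size": clutch,
                    "centred_value": cen,
                    "mean_individual_clutch": s.mean_individual_clutch,
                }
            )
    return pd.DataFrame(rows)


def frame_to_series(df: pd.DataFrame) -> list[IndividualSeries]:
    """Rebuild :class:`IndividualSeries` objects from :func:`series_to_frame` output."""
    out = []
    for ind_id, grp in df.groupby("individual_id", sort=False):
        grp = grp.sort_values("breed_year")
        centred_col = grp["centred_value"].to_numpy(dtype=float)
        centred = None if np.isnan(centred_col).any() else tuple(float(c) for c in centred_col)
        clutches = tuple(
            int(c) if float(c).is_integer() else float(c) for c in grp["clutch_size"]
        )
        out.append(
            IndividualSeries(
                individual_id=str(ind_id),
                population=str(grp["population"].iloc[0]),
                sex=str(grp["sex"].iloc[0]),
                birth_year=int(grp["birth_year"].iloc[0]),
                first_breed_year=int(grp["breed_year"].iloc[0]),
                ages=tuple(int(a) for a in grp["age"]),
                clutch_values=clutches,
                centred_values=centred,
                mean_individual_clutch=float(np.mean(clutches)),
            )
        )
    return out
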