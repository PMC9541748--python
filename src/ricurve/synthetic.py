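"""Individual-based life-history simulator with known RIC ground truth.

Generates breeding-record tables in the ingest schema for populations along
the slow-fast pace-of-life continuum.  Each simulated individual's clutch in
its ``t``-th breeding season (t = 0, 1, ...) is

    clutch_t = round(base + quality_i + u_year(t)
                     + (A_L/2) cos(2 pi t / w_L + phi)
                     + (A_S/2) cos(pi t + psi) + eps_t),  floored at 0

i.e. a population baseline, an individual quality offset, a population-year
environmental effect shared by everyone breeding that year, a long-term
investment wave (wavelength ``w_L`` > 2 years, senescence-like), a
short-term Nyquist alternation (wavelength exactly 2 — the carry-over
signature), and observation noise.  Whether the long or the short component
dominates is drawn per individual (``p_dominant_long``); the dominant
component receives the larger of the two drawn amplitudes, scaled apart by a
minimum dominance margin so that ground-truth dominance stays identifiable
on short, leaky spectra.

Lifespans (number of consecutive breeding seasons) are geometric with the
population's annual adult survival as continuation probability, capped at 9
breeding seasons — short-lived passerine demography.  Fast (deciduous-oak)
presets pair low survival with large clutches and strong, often long-term
waves; slow (evergreen-oak) presets pair high survival with small clutches
and mostly short-term adjustment.

Because cos(pi t + psi) collapses to ((-1)^t) cos(psi) at integer t, a
uniform short-phase would silently rescale the injected short amplitude; the
short phase is therefore drawn from {0, pi} (a random sign) while the
long-mode phase is uniform.

Determinism: one integer seed governs everything; each individual has its
own counter-based substream, so enlarging a population never perturbs
previously generated individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationConfig",
    "TruthRecord",
    "FAST_PRESET",
    "SLOW_PRESET",
    "default_study_configs",
    "simulate_individual",
    "simulate_study",
]

MAX_LIFESPAN = 9  # breeding seasons; observed ages run 1-9 in this system
DOMINANCE_MARGIN = 1.5  # dominant amplitude >= margin * secondary amplitude


@dataclass(frozen=True)
class PopulationConfig:
    """Simulation parameters for one population (units: eggs and years)."""

    label: str
    annual_survival: float
    base_clutch: float
    long_amplitude_mean: float = 2.5
    short_amplitude_mean: float = 1.5
    p_dominant_long: float = 0.5
    long_wavelength_choices: tuple[float, ...] = (4.0, 6.0)
    year_effect_sd: float = 0.5
    quality_sd: float = 0.5
    noise_sd: float = 0.7

    def validate(self) -> None:
        if not 0.0 < self.annual_survival < 1.0:
            raise ValueError(f"{self.label}: annual_survival must be in (0, 1)")
        if not 0.0 <= self.p_dominant_long <= 1.0:
            raise ValueError(f"{self.label}: p_dominant_long must be in [0, 1]")
        for name in ("year_effect_sd", "quality_sd", "noise_sd",
                     "long_amplitude_mean", "short_amplitude_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.label}: {name} must be >= 0")
        if any(w <= 2.0 for w in self.long_wavelength_choices):
            raise ValueError(f"{self.label}: long wavelengths must exceed 2 years")


#: Fast pace-of-life preset: low adult survival, large clutches, accumulated
#: (long-term) reproductive costs dominate in most individuals.
FAST_PRESET = PopulationConfig(
    label="fast", annual_survival=0.45, base_clutch=9.5,
    long_amplitude_mean=3.0, short_amplitude_mean=1.8, p_dominant_long=0.7,
)

#: Slow preset: high adult survival, small clutches, costs paid year-to-year.
SLOW_PRESET = PopulationConfig(
    label="slow", annual_survival=0.56, base_clutch=6.5,
    long_amplitude_mean=2.0, short_amplitude_mean=1.6, p_dominant_long=0.3,
)


def default_study_configs() -> list[PopulationConfig]:
    """Four populations emulating the blue tit study system: two fast
    deciduous-oak populations and two slow evergreen-oak populations."""
    return [
        PopulationConfig("D-Rouviere", 0.45, 9.5, 3.0, 1.8, 0.65),
        PopulationConfig("D-Muro", 0.45, 8.5, 2.8, 1.8, 0.60),
        PopulationConfig("E-Muro", 0.56, 7.0, 2.0, 1.6, 0.50),
        PopulationConfig("E-Pirio", 0.56, 6.5, 2.0, 1.6, 0.45),
    ]


@dataclass(frozen=True)
class TruthRecord:
    individual_id: str
    population: str
    true_dominant_scale: str
    true_long_wavelength: float
    true_long_amplitude: float
    true_short_amplitude: float
    lifespan: int
    quality: float


def _draw_lifespan(rng: np.random.Generator, survival: float) -> int:
    life = 1
    while life < MAX_LIFESPAN and rng.random() < survival:
        life += 1
    return life


def _draw_amplitude(rng: np.random.Generator, mean: float) -> float:
    if mean <= 0:
        return 0.0
    # gamma with shape 4: positive, mildly right-skewed, CV = 0.5
    return float(rng.gamma(4.0, mean / 4.0))


def simulate_individual(
    config: PopulationConfig,
    rng: np.random.Generator,
    individual_id: str = "ind",
    year_effects: Sequence[float] | None = None,
    round_clutches: bool = True,
    align_wavelengths: bool = False,
    overrides: dict | None = None,
) -> tuple[np.ndarray, TruthRecord]:
    """Simulate one individual's clutch series and its ground truth.

    ``year_effects``, when given, supplies the shared environmental effect
    for each of the individual's breeding seasons (length >= lifespan);
    otherwise the effects are drawn i.i.d. from the individual's own stream.

    ``align_wavelengths`` puts both injected sinusoids exactly on DFT bins
    of the realized series (even lifespan of at least 4; long wavelength a
    divisor of the lifespan).  Spectral leakage then vanishes and ground
    truth is exactly identifiable — the regime the recovery tests run in.

    ``overrides`` pins any of ``lifespan``, ``quality``, ``dominant_long``,
    ``long_amplitude``, ``short_amplitude``, ``long_wavelength``,
    ``long_phase``, ``short_phase`` instead of drawing them (controlled
    injection for tests).
    """
    config.validate()
    ov = overrides or {}
    life = int(ov.get("lifespan", _draw_lifespan(rng, config.annual_survival)))
    if align_wavelengths and life >= 3 and "lifespan" not in ov:
        life = min(life + (life % 2), MAX_LIFESPAN - 1)  # even, 4..8
    quality = float(
        ov.get("quality",
               rng.normal(0.0, config.quality_sd) if config.quality_sd > 0 else 0.0)
    )

    dominant_long = bool(ov.get("dominant_long", rng.random() < config.p_dominant_long))
    a_long = float(ov.get("long_amplitude", _draw_amplitude(rng, config.long_amplitude_mean)))
    a_short = float(ov.get("short_amplitude", _draw_amplitude(rng, config.short_amplitude_mean)))
    if "long_amplitude" not in ov and "short_amplitude" not in ov:
        hi, lo = max(a_long, a_short), min(a_long, a_short)
        lo = min(lo, hi / DOMINANCE_MARGIN)
        if dominant_long:
            a_long, a_short = hi, lo
        else:
            a_long, a_short = lo, hi

    choices = np.asarray(config.long_wavelength_choices, dtype=float)
    if align_wavelengths:
        divisors = choices[(life % choices.astype(int)) == 0] if life >= 4 else choices
        choices = divisors if divisors.size else np.array([float(life)])
    w_long = float(ov.get("long_wavelength", rng.choice(choices)))
    phi = float(ov.get("long_phase", rng.uniform(-np.pi, np.pi)))
    psi = float(ov.get("short_phase", 0.0 if rng.random() < 0.5 else np.pi))

    t = np.arange(life)
    if year_effects is None:
        u = (rng.normal(0.0, config.year_effect_sd, size=life)
             if config.year_effect_sd > 0 else np.zeros(life))
    else:
        u = np.asarray(year_effects, dtype=float)[:life]
    eps = (rng.normal(0.0, config.noise_sd, size=life)
           if config.noise_sd > 0 else np.zeros(life))

    clutch = (
        config.base_clutch + quality + u
        + (a_long / 2.0) * np.cos(2.0 * np.pi * t / w_long + phi)
        + (a_short / 2.0) * np.cos(np.pi * t + psi)
        + eps
    )
    if round_clutches:
        clutch = np.floor(clutch + 0.5)  # round half up, as egg counts
    clutch = np.maximum(clutch, 0.0)

    truth = TruthRecord(
        individual_id=individual_id,
        population=config.label,
        true_dominant_scale="long" if dominant_long else "short",
        true_long_wavelength=w_long,
        true_long_amplitude=a_long,
        true_short_amplitude=a_short,
        lifespan=life,
        quality=quality,
    )
    return clutch, truth


def _substream(seed: int, pop_index: int, ind_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(pop_index, ind_index))
    )


def simulate_study(
    configs: Sequence[PopulationConfig],
    n_individuals: int,
    seed: int,
    start_year: int = 2000,
    n_recruit_years: int = 12,
    round_clutches: bool = True,
    align_wavelengths: bool = False,
    p_second: float = 0.02,
    p_replacement: float = 0.10,
    p_polygamous: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-population study as a breeding-record table.

    Year effects are shared within population-year (so mean-centring is
    meaningful); recruitment is staggered uniformly over
    ``n_recruit_years``.  A small fraction of extra second/replacement
    clutch rows and of polygamous individuals is included so the ingest
    filters have realistic work to do; the returned table conforms to the
    ingest CSV schema.  Individuals with lifespan < 3 are included (the
    pipeline must drop them).

    Returns ``(records, truth)`` data frames.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    for cfg in configs:
        cfg.validate()

    max_year = start_year + n_recruit_years + MAX_LIFESPAN
    rec_rows: list[dict] = []
    truth_rows: list[dict] = []
    for p_idx, cfg in enumerate(configs):
        # population-level stream: shared year effects, one per calendar year
        pop_rng = _substream(seed, p_idx, 0)
        years = np.arange(start_year, max_year + 1)
        u_by_year = dict(
            zip(years.tolist(),
                (pop_rng.normal(0.0, cfg.year_effect_sd, size=years.size)
                 if cfg.year_effect_sd > 0 else np.zeros(years.size)).tolist())
        )
        for i in range(n_individuals):
            rng = _substream(seed, p_idx, i + 1)
            ind_id = f"{cfg.label}_{i:05d}"
            first_year = int(rng.integers(start_year, start_year + n_recruit_years))
            sex = "female" if rng.random() < 0.5 else "male"
            polygamous = rng.random() < p_polygamous

            # shared year effects aligned to calendar years; hand the
            # individual a window long enough for any possible lifespan
            window = [u_by_year[first_year + j] for j in range(MAX_LIFESPAN)]
            clutch, truth = simulate_individual(
                cfg, rng, individual_id=ind_id, year_effects=window,
                round_clutches=round_clutches, align_wavelengths=align_wavelengths,
            )
            birth_year = first_year - 1
            for j, c in enumerate(clutch):
                rec_rows.append(
                    {
                        "individual_id": ind_id,
                        "population": cfg.label,
                        "sex": sex,
                        "birth_year": birth_year,
                        "breed_year": first_year + j,
                        "age": j + 1,
                        "clutch_size": int(c) if round_clutches else float(c),
                        "clutch_type": "first",
                        "polygamous": polygamous,
                        # ground-truth environmental effect, ignored by ingest
                        "true_year_effect": u_by_year[first_year + j],
                    }
                )
                # occasional extra non-first clutches in the same season
                extra = rng.random()
                if extra < p_second:
                    ctype = "second"
                elif extra < p_second + p_replacement:
                    ctype = "replacement"
                else:
                    ctype = None
                if ctype is not None:
                    rec_rows.append(
                        {
                            "individual_id": ind_id,
                            "population": cfg.label,
                            "sex": sex,
                            "birth_year": birth_year,
                            "breed_year": first_year + j,
                            "age": j + 1,
                            "clutch_size": max(int(c) - int(rng.integers(1, 4)), 1),
                            "clutch_type": ctype,
                            "polygamous": polygamous,
                        }
                    )
            truth_rows.append({**asdict(truth)})
    records = pd.DataFrame(rec_rows)
    truth = pd.DataFrame(truth_rows)
    return records, truth
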