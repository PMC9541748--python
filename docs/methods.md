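# Methods

## Model and assumptions

`ricurve` treats an individual's sequence of annual clutch sizes as a short,
regularly sampled time series and asks over what timescale reproductive
investment changes.  The decomposition is the plain discrete Fourier
transform of the demeaned series, `c_k = Σ_t y_t exp(−2πikt/n)` with one
sample per year and candidate frequencies `k = 1 … ⌊n/2⌋`.  No zero-padding,
windowing, tapering or detrending beyond demeaning is applied: the series
are 3–9 points long, and the untouched DFT has the property the analysis
relies on — the modes plus the mean reconstruct the observed series exactly
(enforced to 1e-9 in the tests, along with Parseval's identity for the
per-mode variance shares).

Interpretation rests on three conventions:

* **Amplitude** is reported peak-to-trough (`2·a_k`, where `a_k = 2|c_k|/n`,
  or `|c_k|/n` at the Nyquist bin), i.e. the total swing in eggs, twice the
  mathematical sine amplitude.
* **Wavelength** is `n/k` years and is not constrained to integers
  (e.g. 2.5 at n = 5).
* **Short vs long**: a wavelength of exactly 2 years (tolerance 1e-9) is the
  Nyquist alternation and is classified short-term; everything longer is
  long-term.  A configurable alternative (`below_4`) classifies anything
  under 4 years as short, as a robustness variant.  Phase is computed and
  reported but never interpreted — the DFT is non-directional on these
  short windows, so nothing is claimed about *when* within a life peaks
  occur.

Ties in amplitude between modes are resolved toward the longer wavelength,
deterministically.  A mode is counted as *present* only if its
peak-to-trough amplitude exceeds 1e-9 eggs; zero-amplitude bins are
mathematical placeholders, not strategies, and a constant series has no
classifiable strategy at all.

## Data assembly

Input is a long-format table of breeding attempts.  Second clutches,
replacement clutches and polygamous pairings are excluded outright (they
reflect a different investment decision than a single first clutch).
Individuals with an interior gap in their breeding years are dropped
entirely — a missing year cannot be distinguished from breeding outside the
study area — whereas terminal truncation (death, emigration) never causes
exclusion.  Series shorter than three attempts carry no oscillatory signal
and are dropped.  Every series is analysed on two scales: absolute clutch
size, and the deviation from the population-year mean clutch
("mean-centred"), which removes environmental variation shared by all
individuals breeding in the same population and year.

Two assembly choices were genuinely open and are fixed as follows.
Population-year means are computed from *all* first-clutch records,
including individuals later dropped for gaps or short series, because the
environmental average should use the full population sample; and the focal
individual's own record is included in its population-year mean (standard
centring).  The lifetime mean clutch of each individual is carried as a
quality covariate.  Ages and birth years are taken as supplied in the data;
birth year is used only as a random-effect grouping label.

## Inference

Three responses are modelled per clutch-size measure: the binary dominant
timescale (0 short / 1 long, logistic link) and the peak-to-trough
amplitudes of the short- and long-term RICs (Gaussian, log-transformed for
the absolute measure, square-root for the centred one — chosen to make
residuals approximately Gaussian given the right-skew of amplitudes).
An individual contributes to an amplitude response only if one of its two
leading RICs has that scale; rows with zero amplitude are dropped before a
log transform and counted in the run metadata.

Every candidate model carries a birth-year random intercept and one of the
2³ subsets of {mean individual clutch size, population, sex}.  All fits are
maximum likelihood (not REML) so that AICc is comparable across fixed-effect
structures.  The parameter count `k` in
`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)` is fixed effects + random-intercept
variance (+ residual variance for Gaussian families), which reproduces the
df bookkeeping of standard mixed-model selection tables (intercept-only
binary model: k = 2).  Models within ΔAICc < 2 of the best are retained;
their Akaike weights are renormalised and coefficients averaged
*conditionally* (a term is averaged only over retained models containing
it).  Full averaging (absent terms set to zero) is available behind a flag;
the choice is recorded in the run metadata.  Estimated marginal means are
computed from the single best model, with other factors averaged with equal
level weights on the link scale, the continuous covariate at its grand mean
and the random effect at zero, then back-transformed (inverse logit / exp /
square) with delta-method standard errors.  Reference levels default to
population `D-Muro` and sex `female`.

The Gaussian mixed models are fitted with statsmodels `MixedLM`
(`reml=False`), with an optimizer cascade and an exact fallback: when the
between-cohort variance degenerates to the boundary, the zero-variance
profile (OLS with ML scale) is used whenever it does not lose likelihood, so
the variance estimate is exactly 0 rather than numerically unstable.  The
logistic random-intercept model is fitted by direct maximisation of the
Gauss–Hermite marginal likelihood (25 nodes, σ constrained to [0, ∞)); the
quadrature is validated in the tests against brute-force numerical
integration, and the σ → 0 limit against plain logistic regression.
Fixed-effect covariances come from the numerical Hessian at the optimum
(with σ held fixed when it sits on the boundary).  Non-converged fits are
excluded from selection with a warning.

## Synthetic data generator

The generator emulates a multi-population nest-box study.  Individual `i`
of population `p` breeding in its `t`-th season lays

```
clutch_t = round(base_p + quality_i + u_{p,year} + (A_L/2)·cos(2πt/w_L + φ)
                 + (A_S/2)·cos(πt + ψ) + ε_t)   (floored at 0)
```

with lifespan geometric in the population's annual adult survival, capped at
nine seasons.  Defaults encode the motivating contrast: two fast
deciduous-oak populations (survival 0.45, large clutches, strong and mostly
long-term waves) and two slow evergreen-oak populations (survival 0.56,
small clutches, mostly short-term adjustment); the preset survivals sit in
the ranges reported for such populations (0.42–0.47 vs 0.55–0.57).  Long
wavelengths are drawn from {4, 6} years; the short component is the Nyquist
alternation.  Year effects (SD 0.5 eggs) are shared by all individuals of a
population breeding in the same calendar year, so mean-centring has
something real to remove; individual quality (SD 0.5) and observation noise
(SD 0.7) round out the variance.  A small fraction of second (2%),
replacement (10%) and polygamous (1%) records is included so the ingest
filters are exercised, mirroring typical field proportions.  Whether the
long or short component dominates is drawn per individual
(`p_dominant_long`); the dominant component receives the larger of the two
drawn amplitudes and the other is scaled to at most 1/1.5 of it, so that
ground-truth dominance has an identifiable margin.

Two deliberate departures from a naive formulation:

* **Short-component phase** is drawn from {0, π} rather than uniformly.  At
  integer sampling `cos(πt + ψ) = (−1)^t cos ψ`, so a uniform ψ would
  silently rescale the injected short amplitude by |cos ψ| and make the
  recorded truth wrong; a random sign preserves both the amplitude and the
  sampling variety the phase is meant to provide.
* **Aligned recovery mode** (`align_wavelengths=True`): lifespans are
  rounded up to even (4–8) and the long wavelength is drawn from the choices
  dividing the lifespan.  Both injected sinusoids then sit exactly on DFT
  bins and ground truth is exactly recoverable.  Outside this regime,
  spectral leakage at odd series lengths moves the alternation's energy to
  wavelengths of 2.2–2.5 years, which no fixed short/long cutoff can assign
  correctly in all cases — so the recovery tests (exact amplitude and
  wavelength recovery, 100% dominant-scale agreement at zero noise, the
  fast/slow prevalence contrast) run in the aligned mode, while all default
  simulations keep the realistic unaligned behaviour.

Determinism: one integer seed governs everything; each individual draws from
its own counter-keyed substream, so enlarging a population never perturbs
previously generated individuals.  Integer rounding of clutches is on by
default (egg counts) and switchable off for exact-recovery work; rounding
perturbs a recovered amplitude by at most one egg.

What passing recovery tests do **not** show: the generator draws stationary
sinusoids plus white noise, whereas real clutch dynamics are non-stationary,
phase-coupled to the environment, and subject to selective appearance and
disappearance; recovery under the generator demonstrates the estimator
chain is correct, not that real data meet its assumptions.  Likewise the
generator's geometric lifespans put roughly half of retained individuals at
exactly three breeding attempts (a single candidate mode of wavelength 3),
so cohort composition statistics from simulated studies reflect that
demography and are not comparable to field cohorts with longer series.

## Numerical choices and problem sizes

Tolerances: reconstruction/Parseval 1e-9; mode presence 1e-9 eggs; the
short-cutoff comparison adds 1e-9 years; AICc requires `n > k + 1`;
zero-variance contract for random intercepts: estimates below 1e-3 are
treated as boundary fits.  Simulation-based tests use 100–1000 individuals
per population and 20 replicates for Monte-Carlo bias checks — sizes at
which binomial/MC error is small relative to the effects being recovered
while the whole suite stays fast.  Degenerate inputs have defined behaviour:
constant series decompose to zero present modes and refuse classification;
empty cohorts halt the pipeline with an explicit error after writing the
filter report.

## Known limitations

* Wavelet or other non-stationary decompositions are out of scope, as are
  survival costs of reproduction and selective appearance/disappearance.
* Missing breeding years are never imputed and skipped breeding is not
  modelled as zero investment.
* With ≤9 observations the wavelength grid is coarse (n/k), and odd-length
  series cannot express a wavelength-2 mode at all; population comparisons
  of timescale composition therefore carry a series-length signature that
  the birth-year random intercept only partly absorbs.
* Amplitude estimated marginal means on the square-root scale can back-
  transform poorly when the linear predictor is near zero (the delta-method
  SE degenerates).
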