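# ricurve

**Temporal structure of reproductive investment from longitudinal breeding
records.**

Life-history theory predicts a trade-off between current and future
reproduction, but "future" has a timescale: an individual may pay the cost of
a large clutch next year (a carry-over effect) or let costs accumulate into a
late-life decline (senescence).  `ricurve` quantifies *when* those costs are
paid.  It decomposes each individual's clutch-size time series into
sinusoidal **reproductive investment curves** (RICs) via the discrete Fourier
transform, classifies individuals by the timescale of their dominant RIC, and
compares populations along the slow–fast pace-of-life continuum with
AICc-based multimodel inference.  It was built for analyses of multi-decade
nest-box studies of hole-nesting passerines (blue tits breeding in deciduous
vs evergreen oak woodland being the motivating system), but applies to any
annual-breeding species with repeated clutch- or litter-size records.

## The method

For an individual observed over `n` consecutive breeding seasons with
demeaned clutch sizes `y_t`, the DFT

```
c_k = Σ_{t=0}^{n−1} y_t exp(−2πikt/n),   k = 1 … ⌊n/2⌋
```

rewrites the series as a sum of sinusoids.  Mode `k` is an RIC with

* **wavelength** `n/k` years — the temporal scale of the investment change;
* **peak-to-trough amplitude** `A_k = 2·(2|c_k|/n)` eggs (half that at the
  Nyquist bin) — the magnitude of the change, defined as peak minus trough,
  i.e. twice the mathematical sine-wave amplitude.

The mode with the largest `A_k` is the **dominant RIC** (ties resolved toward
the longer wavelength), the next the **secondary RIC**.  A wavelength of
exactly 2 years — the Nyquist alternation, a high clutch followed by a low
one — is **short-term**; anything longer is **long-term**.  Clutch size is
analysed both raw ("absolute") and as the deviation from the population-year
mean ("mean-centred"), which removes shared inter-annual environmental
variation.

Per-individual summaries then feed three model families, each fitted by
maximum likelihood with a birth-year random intercept over all 2³ subsets of
the fixed effects {population, sex, mean individual clutch size}:

* dominant timescale (0 = short, 1 = long): logistic mixed model,
* short-term RIC amplitude and long-term RIC amplitude: Gaussian mixed
  models on the log (absolute) or square-root (centred) scale.

Candidates are ranked by `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`, weighted by
Akaike weights `exp(−Δ/2)/Σexp(−Δ/2)`, models within ΔAICc < 2 of the best
are averaged (conditional averaging), and estimated marginal means with
delta-method standard errors are back-transformed to the response scale.

A built-in individual-based simulator generates breeding-record tables with
known ground truth (population contrasts in survival, clutch size and RIC
structure; shared year effects; individual quality; observation noise) so
that every stage of the pipeline is testable by parameter recovery.

## Worked example

```python
import ricurve

series = [6, 7, 9, 10, 9, 7]            # one bird, six consecutive clutches
decomp = ricurve.decompose(series, individual_id="F231", measure="absolute")
for m in decomp.modes:
    print(f"wavelength {m.wavelength:4.1f} yr  peak-to-trough {m.peak_to_trough:4.2f} eggs  "
          f"variance share {m.variance_share:4.2f}")
c = ricurve.classify(decomp)
print("dominant scale:", c.dominant_scale, "| wavelength:", c.dominant_wavelength,
      "| amplitude:", round(c.dominant_amplitude, 2))
r2f, r2q, r2l = ricurve.compare_fits(series, [1, 2, 3, 4, 5, 6])
print(f"variance explained: fourier {r2f:.2f}, quadratic {r2q:.2f}, lag-1 {r2l:.2f}")
```

prints

```
wavelength  6.0 yr  peak-to-trough 4.00 eggs  variance share 1.00
wavelength  2.0 yr  peak-to-trough 0.00 eggs  variance share 0.00
wavelength  3.0 yr  peak-to-trough 0.00 eggs  variance share 0.00
dominant scale: long | wavelength: 6.0 | amplitude: 4.0
variance explained: fourier 1.00, quadratic 0.89, lag-1 0.17
```

This bird's clutches rise and fall once over its six-year life: a single
long-term RIC (wavelength 6, amplitude 4 eggs) explains all the variation —
the spectral signature of a senescence-like trajectory.  A one-year-lag
state-dependent fit, which only sees year-to-year carry-over, explains 17%.

The full pipeline runs from the shell:

```
ricurve all --outdir run1 --seed 42              # simulate → ingest → … → fit
ricurve all --outdir run2 --seed 7 --input my_records.csv --measure both
```

`run1/` then contains the filter report, per-mode and classification tables,
a cohort summary, one AICc selection table per response × measure, averaged
coefficients, estimated marginal means and a manifest with content hashes
(identical seed ⇒ identical hashes).  For example, `run1`'s timescale
selection table (absolute measure) begins

```
                 terms  df       aicc    delta   weight  retained
           (intercept)   2 129.242483 0.000000 0.347292      True
mean_individual_clutch   3 129.647091 0.404608 0.283684      True
                   sex   3 130.778702 1.536219 0.161105      True
```

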