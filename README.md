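# chaostoch

Discriminate chaotic from stochastic time series — and quantify their
temporal correlations — using permutation entropy and a small neural
regressor trained on flicker noise.

## The method

Given a univariate, regularly sampled series, every window of D = 6
consecutive samples is replaced by its *ordinal pattern* (the permutation
describing the rank order of the window). The relative frequencies
𝒫(i) of the 720 possible patterns give two things:

* the **normalized permutation entropy**
  S̄ = −Σᵢ 𝒫(i) ln 𝒫(i) / ln 720 ∈ [0, 1];
* a 720-dimensional feature vector fed to a feed-forward network
  (720 → 64 relu → 1 linear, 46 209 trainable parameters) trained
  exclusively on flicker noise — Gaussian noise with power spectrum
  P(f) ∝ 1/f^α — to regress the correlation exponent, yielding an
  estimate **α_e** for any input series.

Stochastic signals fall on the flicker-noise entropy curve S̄_fn(α);
deterministic chaos, with its forbidden ordinal patterns, falls well
below it. The distance

    Ω(α_e) = |S̄_fn(α_e) − S̄| / S̄_fn(α_e)

is ≈ 0 for stochastic signals and large for chaotic ones; the default
decision rule labels a series chaotic when Ω > 0.1. The separation
survives short series (~10² points), moderate noise contamination, and
works for heavy-tailed noise (ordinal statistics are rank-based).

See `docs/methods.md` for the full model description, parameter
defaults, and known limitations (noisy periodic signals, and the
interpretation of α_e for strongly deterministic inputs).

## Worked example

Build the two reusable artifacts once (a trained weights file and a
calibrated reference curve; ~6 minutes on one CPU), then analyze
anything:

```
chaostoch train --seed 0 --out weights.json
#   held-out MAE = 0.0130 over 1000 series
chaostoch calibrate --seed 0 --out curve.csv

chaostoch simulate --system logistic --n 131072 --seed 7 --out logistic.txt
chaostoch analyze logistic.txt --weights weights.json --curve curve.csv
#   alpha_e   sbar      sbar_fn   omega     label
#   -0.443383 0.629126  0.995352  0.367936  chaotic

chaostoch simulate --system flicker --param alpha=2 --n 131072 --seed 7 --out fn2.txt
chaostoch analyze fn2.txt --weights weights.json --curve curve.csv
#   alpha_e   sbar      sbar_fn   omega     label
#   1.981446  0.859987  0.862240  0.002613  stochastic
```

Reading the logistic line: the map's entropy (S̄ = 0.63) sits far below
the flicker reference at its estimated exponent (S̄_fn = 1.00), giving
Ω = 0.37 ≫ 0.1 → **chaotic**. The flicker series generated with α = 2
lands on its own reference curve (α_e = 1.98, S̄ = 0.860 vs
S̄_fn = 0.862, Ω ≈ 0.003) → **stochastic**.

`chaostoch simulate` covers all benchmark generators (flicker, fBm/fGn,
iid uniform/gaussian/cauchy, the βx/logistic/Schuster/skew-tent maps,
Lorenz x-maxima), and `chaostoch experiment` reruns the scripted
benchmark sweeps (summary table, noise-contamination sweep, summed-map
sweep, length-robustness sweep) as seeded CSV outputs.

The library mirrors the CLI one-to-one (`chaostoch.analyze`,
`chaostoch.train`, `chaostoch.calibrate_curve`, ...); see the module
docstrings.

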