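# exgauss-rt

Ex-Gaussian decomposition of masked-priming response times.

Recognition experiments (here: identifying famous faces and famous names)
produce response-time (RT) distributions with a heavy right tail, so a mean
and standard deviation miss most of what changes between conditions. The
standard remedy in the RT literature is the **ex-Gaussian** model: an RT is
the sum of a Gaussian stage, N(µ, σ), and an exponential stage with mean τ,

```
f(x) = (1/τ) · exp((µ−x)/τ + σ²/(2τ²)) · Φ((x−µ)/σ − σ/τ)
```

with mean µ+τ, variance σ²+τ², and skewness 2τ³/(σ²+τ²)^{3/2}. The τ
component absorbs the tail that would otherwise be discarded as outliers.

This package implements the full analysis chain for a two-country
(Spain/USA), face/name, masked-priming design with four prime types
(identity, related, unrelated of same/different nature):

- **simulation** of trial-level cohorts (2×50 participants, 224 trials each,
  32 condition cells) from condition-wise ex-Gaussian components and hit
  rates, with an optional contaminant fraction outside the analysis window;
- **preprocessing**: inclusive 250–1500 ms trimming (with a warning when ≥5%
  of responses are lost), removal of incorrect responses, pooling of RTs per
  condition cell, and the sample descriptors M, S and t (population moments);
- **fitting**: maximum-likelihood estimation of (µ, σ, τ) by a maximum-ascent
  search started from the moment inversion τ₀ = S·(t/2)^{1/3}, µ₀ = M − τ₀,
  σ₀ = √(S² − τ₀²), stopping when the log-likelihood gradient norm falls
  below ε = 10⁻⁸;
- **goodness of fit**: the Kolmogorov–Smirnov statistic against the fitted
  CDF, calibrated by a parametric bootstrap of 1000 samples (larger p =
  better fit);
- **uncertainty**: sampling ≥1000 points of the iso-likelihood surface half
  a log-likelihood point below the maximum; the per-parameter dispersion of
  that surface is the 1σ uncertainty, ×1.96 for 95% intervals.

## Worked example

```python
import exgauss_rt as xg

# simulate a full cohort and analyse it
trials = xg.generate_cohort(xg.CohortDesign(seed=11))
result = xg.run_pipeline(trials, xg.PipelineConfig(seed=3))
print(result.report[["target_nature", "country", "role", "prime",
                     "hit_pct", "M", "mu", "sigma", "tau",
                     "gof_p", "sd_tau", "n_pooled"]].head(3).round(2))
```

prints

```
  target_nature country  role                  prime  hit_pct       M      mu  sigma     tau  gof_p  sd_tau  n_pooled
0          face   spain  test               identity    80.00  628.54  415.46  21.24  213.07   0.89    9.99       547
1          face   spain  test                related    82.00  674.58  447.75  18.89  226.83   0.74   10.24       560
2          face   spain  test  unrelated_same_nature    85.86  687.35  512.57  85.62  174.78   0.97   10.91       585
```

One row per condition cell: the hit percentage, the pooled sample mean M,
the fitted components (µ, σ, τ) in ms, the bootstrap KS p-value (0.89 means
89% of bootstrap samples from the fitted distribution fit *worse* — a good
fit), the surface-based 1σ uncertainty of τ, and the pooled sample size.
The first cell was generated from (µ=417.56, σ=18.72, τ=227.72); the fit
returns it within a few ms on ~550 pooled trials.

The same chain is available from a shell:

```
exgauss-rt simulate --participants-per-country 50 --seed 11 --out trials.csv
exgauss-rt preprocess --in trials.csv --out clean.csv --report exclusions.json
exgauss-rt report --in trials.csv --out report.tsv --histograms hist.csv
exgauss-rt all --out report.tsv            # simulate + analyse in one go
```

## Layout

| module | contents |
| --- | --- |
| `exgauss_rt.design` | condition table, cohort design, trial simulator |
| `exgauss_rt.preprocess` | trimming, correctness filter, pooling, M/S/t |
| `exgauss_rt.exgauss` | pdf/cdf/moments, likelihood, gradient, MLE |
| `exgauss_rt.gof` | KS statistic, parametric-bootstrap p-value |
| `exgauss_rt.uncertainty` | iso-likelihood surface, parameter uncertainties |
| `exgauss_rt.pipeline` | end-to-end orchestration, report/trial I/O |
| `exgauss_rt.validation` | recovery and coverage studies |
| `exgauss_rt.cli` | `exgauss-rt simulate\|preprocess\|fit\|report\|all` |
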