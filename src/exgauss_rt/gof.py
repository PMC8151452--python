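"""Kolmogorov-Smirnov goodness of fit with a parametric-bootstrap p-value.

The KS statistic is the supremum distance between the empirical CDF of a
pooled RT sample and the fitted ex-Gaussian CDF.  Because the fitted
parameters come from the same data, the asymptotic KS null distribution
does not apply; the p-value is instead calibrated by parametric bootstrap:
draw ``n_boot`` samples of the same size from the fitted distribution and
count how often their KS statistic exceeds the observed one.  The larger
the p-value, the better the fit.

By default each bootstrap sample is compared against the same fixed fitted
parameters.  ``refit=True`` switches to the Lilliefors-style variant that
refits every bootstrap sample before computing its KS statistic — the
statistically conservative choice, at roughly the cost of ``n_boot``
additional fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exgauss import (
    ExGaussParams,
    InsufficientDataError,
    SeedLike,
    as_generator,
    exgauss_cdf,
    fit_mle,
)

__all__ = ["GoFResult", "ks_statistic", "bootstrap_pvalue"]


@dataclass(frozen=True)
class GoFResult:
    ks_statistic: float
    p_value: float
    n_boot: int
    refit: bool


def ks_statistic(rts, p: ExGaussParams) -> float:
    """sup_x |ECDF(x) - F(x)| against the fitted CDF F."""
    x = np.sort(np.asarray(rts, dtype=float))
    n = x.size
    if n < 1:
        raise InsufficientDataError("KS statistic of an empty sample")
    F = exgauss_cdf(x, p)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - F, F - (i - 1) / n)))


def _ks_many(samples: np.ndarray, p: ExGaussParams) -> np.ndarray:
    """Row-wise KS statistics of an (m, n) matrix of samples against F."""
    m, n = samples.shape
    F = exgauss_cdf(np.sort(samples, axis=1), p)
    i = np.arange(1, n + 1)
    return np.max(np.maximum(i / n - F, F - (i - 1) / n), axis=1)


def bootstrap_pvalue(
    rts,
    p: ExGaussParams,
    n_boot: int = 1000,
    refit: bool = False,
    seed: SeedLike = None,
) -> GoFResult:
    """Parametric-bootstrap p-value of the KS statistic.

    p = fraction of the ``n_boot`` bootstrap KS statistics that exceed the
    observed one ("bigger than"), with exact ties counted toward the larger
    p-value.  Seeded for reproducibility.
    """
    x = np.asarray(rts, dtype=float)
    n = x.size
    if n < 10:
        raise InsufficientDataError(f"need at least 10 observations for bootstrap GoF, got {n}")
    d_obs = ks_statistic(x, p)
    rng = as_generator(seed)

    draws = rng.normal(p.mu, p.sigma, (n_boot, n)) + rng.exponential(p.tau, (n_boot, n))
    if refit:
        d_boot = np.empty(n_boot)
        for b in range(n_boot):
            fit_b = fit_mle(draws[b])
            d_boot[b] = ks_statistic(draws[b], fit_b.params)
    else:
        d_boot = _ks_many(draws, p)

    p_value = float(np.count_nonzero(d_boot >= d_obs) / n_boot)
    return GoFResult(ks_statistic=d_obs, p_value=p_value, n_boot=n_boot, refit=refit)
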