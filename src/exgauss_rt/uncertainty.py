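"""Parameter uncertainties from the iso-likelihood surface.

In the 3-D parameter space (mu, sigma, tau), the set of points whose
log-likelihood sits half a point below the maximum bounds the ~68%
confidence region of a single parameter (the likelihood-ratio rule with
one degree of freedom: 2*DeltaLogL = 1).  The surface is sampled by
shooting random rays from the MLE and bisecting each ray for the radius
where the log-likelihood crosses ``max - delta``.  Directions are drawn
uniformly on the sphere after per-axis curvature scaling, so strongly
elongated surfaces (the mu-tau trade-off) are sampled evenly.

The 1-sigma uncertainty of each parameter is half the range of that
coordinate over the surface points — the Monte-Carlo estimate of the
profile-likelihood bound, which under a quadratic log-likelihood equals
the Wald standard error.  Multiplying by 1.96 yields 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr

from .exgauss import (
    ExGaussParams,
    FitResult,
    SeedLike,
    as_generator,
    log_likelihood,
    numerical_hessian,
)

__all__ = [
    "SurfacePointSet",
    "UncertaintyResult",
    "SurfaceFailureError",
    "sample_surface",
    "parameter_uncertainties",
]

#: give up on a ray after this many scaled units without a crossing
_MAX_RADIUS = 1e3
#: |loglik - target| tolerance of the bisection root
_ROOT_TOL = 1e-7


class SurfaceFailureError(RuntimeError):
    """The likelihood never drops to the target along the sampled rays."""


@dataclass(frozen=True)
class SurfacePointSet:
    """Points on the iso-likelihood surface, as an (n_points, 3) array of
    (mu, sigma, tau) rows."""

    points: np.ndarray
    target_loglik: float
    n_points: int


@dataclass(frozen=True)
class UncertaintyResult:
    sd_mu: float
    sd_sigma: float
    sd_tau: float
    ci95_mu: tuple[float, float]
    ci95_sigma: tuple[float, float]
    ci95_tau: tuple[float, float]


def _loglik_many(thetas: np.ndarray, x: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Log-likelihood of the data under each (mu, sigma, tau) row."""
    out = np.empty(thetas.shape[0])
    for s in range(0, thetas.shape[0], chunk):
        t = thetas[s : s + chunk]
        mu, sg, ta = t[:, 0:1], t[:, 1:2], t[:, 2:3]
        z = (x[None, :] - mu) / sg - sg / ta
        out[s : s + chunk] = np.sum(
            -np.log(ta) + (mu - x[None, :]) / ta + 0.5 * (sg / ta) ** 2 + log_ndtr(z),
            axis=1,
        )
    return out


def _axis_scales(x: np.ndarray, p: ExGaussParams) -> np.ndarray:
    """Per-axis curvature scales sqrt(diag(-H)^-1); dispersion-based fallback
    when the Hessian is not negative definite (flat or saddle at the MLE)."""
    H = numerical_hessian(x, p)
    try:
        cov = np.linalg.inv(-H)
        diag = np.diag(cov)
        if np.all(np.isfinite(diag)) and np.all(diag > 0.0):
            return np.sqrt(diag)
    except np.linalg.LinAlgError:
        pass
    S = float(np.std(x))
    return np.array([S, S, S]) / np.sqrt(x.size)


def sample_surface(
    rts,
    fit: FitResult,
    delta: float = 0.5,
    n_points: int = 1024,
    seed: SeedLike = None,
) -> SurfacePointSet:
    """Sample ``n_points`` points where the log-likelihood equals
    ``max - delta``.

    Rays that exit the positive-sigma/tau domain before crossing the target
    are redrawn; a ray still above the target after 1e3 scaled units means
    the likelihood is flat and raises ``SurfaceFailureError``.
    """
    if not fit.converged:
        raise ValueError("surface sampling requires a converged fit")
    if n_points < 1000:
        raise ValueError(f"need at least 1000 surface points, got {n_points}")
    if delta <= 0.0:
        raise ValueError("delta must be positive")

    x = np.asarray(rts, dtype=float)
    theta0 = fit.params.as_array()
    ll_max = log_likelihood(x, fit.params)
    target = ll_max - delta
    scales = _axis_scales(x, fit.params)
    rng = as_generator(seed)

    collected: list[np.ndarray] = []
    need = n_points
    for _ in range(200):
        if need <= 0:
            break
        u = rng.standard_normal((need, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        d = u * scales

        # largest radius keeping sigma and tau strictly positive
        with np.errstate(divide="ignore"):
            lim = np.where(d[:, 1:] < 0.0, theta0[1:] / -d[:, 1:], np.inf)
        r_cap = np.minimum(np.min(lim, axis=1) * (1.0 - 1e-9), _MAX_RADIUS)

        ll_cap = _loglik_many(theta0 + r_cap[:, None] * d, x)
        no_cross = ll_cap > target
        if np.any(no_cross & (r_cap >= _MAX_RADIUS)):
            raise SurfaceFailureError(
                f"log-likelihood stays within {delta} of the maximum beyond "
                f"{_MAX_RADIUS:g} scaled units; surface undefined"
            )
        keep = ~no_cross  # domain-limited rays are redrawn next round
        d, r_cap = d[keep], r_cap[keep]

        lo = np.zeros(d.shape[0])
        hi = r_cap.copy()
        r = 0.5 * (lo + hi)
        active = np.ones(d.shape[0], dtype=bool)
        for _ in range(120):
            ll_mid = _loglik_many(theta0 + r[active][:, None] * d[active], x)
            res = ll_mid - target
            above = res > 0.0
            idx = np.flatnonzero(active)
            lo[idx[above]] = r[idx[above]]
            hi[idx[~above]] = r[idx[~above]]
            done = np.abs(res) <= _ROOT_TOL
            active[idx[done]] = False
            if not active.any():
                break
            r[active] = 0.5 * (lo[active] + hi[active])
        collected.append(theta0 + r[:, None] * d)
        need = n_points - sum(c.shape[0] for c in collected)

    points = np.vstack(collected)[:n_points]
    if points.shape[0] < n_points:
        raise SurfaceFailureError(
            "could not place the requested number of surface points inside "
            "the positive-sigma/tau domain"
        )
    return SurfacePointSet(points=points, target_loglik=target, n_points=n_points)


def parameter_uncertainties(surface: SurfacePointSet, fit: FitResult) -> UncertaintyResult:
    """Per-parameter dispersion of the surface and the derived 95% intervals.

    The 1-sigma uncertainty is half the coordinate range of the surface
    along each axis; the 95% interval is the MLE +- 1.96 times that.
    """
    half_range = 0.5 * (surface.points.max(axis=0) - surface.points.min(axis=0))
    mle = fit.params.as_array()
    lo = mle - 1.96 * half_range
    hi = mle + 1.96 * half_range
    return UncertaintyResult(
        sd_mu=float(half_range[0]),
        sd_sigma=float(half_range[1]),
        sd_tau=float(half_range[2]),
        ci95_mu=(float(lo[0]), float(hi[0])),
        ci95_sigma=(float(lo[1]), float(hi[1])),
        ci95_tau=(float(lo[2]), float(hi[2])),
    )
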