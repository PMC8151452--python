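"""End-to-end orchestration: trim, filter, pool, fit, test, report.

``run_pipeline`` turns a trial-level table into one report row per
condition cell, mirroring the reference layout: hit %, sample descriptors
(M, S, t), fitted components (mu, sigma, tau) and the bootstrap
goodness-of-fit p, optionally followed by the surface-based parameter
uncertainties.  Hit rates are computed on all trials of a cell before RT
trimming; the RT analysis then uses correct, in-window responses only.

Cells whose pooled sample is too small, or whose fit does not converge,
degrade to a non-``ok`` status instead of aborting the run.  All
randomness (bootstrap draws, surface directions) derives from the single
configured seed, so a report is reproducible byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import CONDITION_KEYS, TRIAL_COLUMNS
from .exgauss import fit_mle
from .gof import bootstrap_pvalue
from .preprocess import (
    KEY_COLUMNS,
    ExclusionReport,
    compute_sample_stats,
    filter_correct,
    pool_by_condition,
    trim_rts,
)
from .uncertainty import SurfaceFailureError, parameter_uncertainties, sample_surface

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "SchemaError",
    "run_pipeline",
    "read_trials",
    "write_report",
    "histogram_counts",
    "write_histograms",
]

logger = logging.getLogger("exgauss_rt")

REPORT_COLUMNS = [
    "target_nature",
    "country",
    "role",
    "prime",
    "hit_pct",
    "M",
    "S",
    "t",
    "mu",
    "sigma",
    "tau",
    "gof_p",
    "sd_mu",
    "sd_sigma",
    "sd_tau",
    "n_pooled",
    "status",
]

_VALID = {
    "country": {"spain", "usa"},
    "target_nature": {"face", "name"},
    "role": {"test", "distracting"},
    "prime": {
        "identity",
        "related",
        "unrelated_same_nature",
        "unrelated_different_nature",
    },
}


class SchemaError(ValueError):
    """A trial CSV violates the expected schema."""


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis settings; the defaults are the reference procedure:
    250-1500 ms trimming, eps = 1e-8 gradient stop, 1000 bootstrap
    samples, >= 1000 surface points at delta = 0.5, 1.96x for 95% CIs."""

    lower_ms: float = 250.0
    upper_ms: float = 1500.0
    eps: float = 1e-8
    max_iter: int = 100_000
    n_boot: int = 1000
    gof_refit: bool = False
    surface_points: int = 1024
    surface_delta: float = 0.5
    compute_uncertainties: bool = True
    min_cell_n: int = 10
    hist_bin_ms: float = 50.0
    seed: int = 0

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return PipelineConfig(**raw)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


@dataclass(frozen=True)
class PipelineResult:
    report: pd.DataFrame
    exclusions: ExclusionReport
    pools: dict = field(repr=False)


def _cell_seed(master: int, index: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([master, index, stream])


def run_pipeline(trials: pd.DataFrame, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Full analysis of a trial table; one report row per observed cell."""
    if len(trials) == 0:
        raise ValueError("empty trial table")

    # hit rates per cell on all (non-practice) trials, before RT trimming
    hit = trials.groupby(KEY_COLUMNS, sort=False, observed=True)["correct"].mean()

    trimmed, excl = trim_rts(trials, config.lower_ms, config.upper_ms)
    n_after_trim = len(trimmed)
    kept = filter_correct(trimmed)
    excl = ExclusionReport(
        n_total=excl.n_total,
        n_rt_excluded=excl.n_rt_excluded,
        n_incorrect_excluded=n_after_trim - len(kept),
        fraction_rt_excluded=excl.fraction_rt_excluded,
        warning_flag=excl.warning_flag,
    )
    pools = pool_by_condition(kept)

    rows = []
    for idx, key in enumerate(CONDITION_KEYS):
        rts = pools[key]
        levels = (key.target_nature, key.country, key.role, key.prime)
        if levels not in hit.index:
            continue  # cell absent from the input design
        row: dict = dict(zip(KEY_COLUMNS, levels))
        row["hit_pct"] = 100.0 * float(hit.loc[levels])
        row["n_pooled"] = int(rts.size)
        if rts.size < config.min_cell_n:
            row["status"] = "insufficient_data"
            rows.append(row)
            continue

        stats = compute_sample_stats(rts)
        row.update(M=stats.M, S=stats.S, t=stats.t)
        fit = fit_mle(rts, eps=config.eps, max_iter=config.max_iter)
        logger.info(
            "cell %s/%s/%s/%s: n=%d, %d iterations, |grad|=%.2e, converged=%s",
            *levels, rts.size, fit.iterations, fit.gradient_norm, fit.converged,
        )
        if not fit.converged:
            row["status"] = "not_converged"
            rows.append(row)
            continue
        p = fit.params
        row.update(mu=p.mu, sigma=p.sigma, tau=p.tau)

        gof = bootstrap_pvalue(
            rts, p,
            n_boot=config.n_boot,
            refit=config.gof_refit,
            seed=_cell_seed(config.seed, idx, 1),
        )
        row["gof_p"] = gof.p_value

        if config.compute_uncertainties:
            try:
                surf = sample_surface(
                    rts, fit,
                    delta=config.surface_delta,
                    n_points=config.surface_points,
                    seed=_cell_seed(config.seed, idx, 2),
                )
                unc = parameter_uncertainties(surf, fit)
                row.update(sd_mu=unc.sd_mu, sd_sigma=unc.sd_sigma, sd_tau=unc.sd_tau)
            except SurfaceFailureError as err:
                logger.warning("cell %s/%s/%s/%s: %s", *levels, err)
        row["status"] = "ok"
        rows.append(row)

    report = pd.DataFrame(rows).reindex(columns=REPORT_COLUMNS)
    return PipelineResult(report=report, exclusions=excl, pools=pools)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV (schema of ``design.write_trials``).

    Raises ``SchemaError`` naming the offending column and CSV line on the
    first violation found.
    """
    try:
        df = pd.read_csv(path)
    except OSError as err:
        raise SchemaError(f"cannot read trial table {path}: {err}") from err
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table {path} lacks columns {missing}")
    df = df[TRIAL_COLUMNS]

    for col, allowed in _VALID.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"column '{col}', line {i + 2}: invalid value {df[col].iat[i]!r}"
            )
    for col, check in [
        ("rt_ms", lambda s: (s > 0) & np.isfinite(s)),
        ("correct", lambda s: s.isin([0, 1])),
    ]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~check(vals)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"column '{col}', line {i + 2}: invalid value {df[col].iat[i]!r}"
            )
    return df


def write_report(report: pd.DataFrame, path) -> None:
    """Write the report as TSV in reference column order, p to two decimals."""
    out = report.copy()
    if "gof_p" in out.columns:
        out["gof_p"] = out["gof_p"].map(lambda v: "" if pd.isna(v) else f"{v:.2f}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.2f", encoding="utf-8")


def histogram_counts(
    pools: dict, bin_ms: float = 50.0, lower: float = 250.0, upper: float = 1500.0
) -> pd.DataFrame:
    """Histogram-ready per-cell binned counts (output only; the fitter always
    consumes raw response times)."""
    edges = np.arange(lower, upper + bin_ms, bin_ms)
    frames = []
    for key, rts in pools.items():
        if rts.size == 0:
            continue
        counts, _ = np.histogram(rts, bins=edges)
        frames.append(
            pd.DataFrame(
                {
                    "target_nature": key.target_nature,
                    "country": key.country,
                    "role": key.role,
                    "prime": key.prime,
                    "bin_left_ms": edges[:-1],
                    "bin_right_ms": edges[1:],
                    "count": counts,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_histograms(pools: dict, path, bin_ms: float = 50.0) -> None:
    histogram_counts(pools, bin_ms=bin_ms).to_csv(path, index=False, encoding="utf-8")
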