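"""Exclusion rules and descriptive statistics for trial-level RT tables.

Response times outside the 250-1500 ms window are trimmed (bounds
inclusive: the rules exclude times strictly below/above the cut-offs) and
incorrect responses are dropped; for distractor stimuli "correct" means a
correct rejection.  The two filters commute.  Trimming aims to remove fewer
than 5% of responses, so crossing that fraction raises a warning flag but
never aborts.

The descriptors (M, S, t) are population moments: S divides by n, and
t is the third central moment over S^3.  This keeps the moment inversion
used for the fitter's starting values (tau0 = S*(t/2)^(1/3)) exactly
consistent with how the statistics are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CONDITION_KEYS, ConditionKey
from .exgauss import InsufficientDataError

__all__ = [
    "ExclusionReport",
    "SampleStats",
    "TrimWarning",
    "trim_rts",
    "filter_correct",
    "pool_by_condition",
    "compute_sample_stats",
]

KEY_COLUMNS = ["target_nature", "country", "role", "prime"]


class TrimWarning(UserWarning):
    """Emitted when trimming excludes at least 5% of the responses."""


@dataclass(frozen=True)
class ExclusionReport:
    n_total: int
    n_rt_excluded: int
    n_incorrect_excluded: int
    fraction_rt_excluded: float
    warning_flag: bool


@dataclass(frozen=True)
class SampleStats:
    """Pooled-sample descriptors: mean M, population SD S, skewness t, size n."""

    n: int
    M: float
    S: float
    t: float


def trim_rts(
    trials: pd.DataFrame, lower: float = 250.0, upper: float = 1500.0
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Keep trials with lower <= rt_ms <= upper; report what was cut."""
    if not lower < upper:
        raise ValueError(f"trimming window is empty: lower={lower}, upper={upper}")
    n_total = len(trials)
    keep = trials["rt_ms"].between(lower, upper)
    kept = trials.loc[keep]
    n_excl = int(n_total - len(kept))
    frac = n_excl / n_total if n_total else 0.0
    flag = frac >= 0.05
    if flag:
        warnings.warn(
            f"trimming removed {frac:.1%} of responses (aim is < 5%)", TrimWarning,
            stacklevel=2,
        )
    return kept, ExclusionReport(n_total, n_excl, 0, frac, flag)


def filter_correct(trials: pd.DataFrame) -> pd.DataFrame:
    """Retain correct responses only (order preserved; idempotent)."""
    return trials.loc[trials["correct"].astype(bool)]


def pool_by_condition(trials: pd.DataFrame) -> dict[ConditionKey, np.ndarray]:
    """Concatenate RTs across participants within each of the 32 cells.

    Every canonical condition key is present in the result; cells without
    data map to empty vectors.
    """
    pools: dict[ConditionKey, np.ndarray] = {
        key: np.empty(0, dtype=float) for key in CONDITION_KEYS
    }
    for levels, grp in trials.groupby(KEY_COLUMNS, sort=False, observed=True):
        key = ConditionKey(*levels)
        pools[key] = grp["rt_ms"].to_numpy(dtype=float)
    return pools


def compute_sample_stats(rts) -> SampleStats:
    """Population-moment descriptors M, S, t of a pooled RT vector."""
    x = np.asarray(rts, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"need n >= 2 for sample statistics, got {n}")
    M = float(np.mean(x))
    dev = x - M
    S = float(np.sqrt(np.mean(dev**2)))
    if S == 0.0:
        raise InsufficientDataError("zero-variance sample: skewness undefined")
    t = float(np.mean(dev**3) / S**3)
    return SampleStats(n=n, M=M, S=S, t=t)
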