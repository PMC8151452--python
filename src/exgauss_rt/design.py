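"""Masked-priming study design and trial-level simulator.

The emulated experiment: two country groups (Spain, USA) of 50 university
students each classify famous faces and famous names ("test" stimuli, to be
identified) against unknown distractors ("distracting" stimuli, to be
rejected) after a masked prime.  Primes come in four flavours: identity,
related (same celebrity, other nature), and unrelated primes of the same or
of a different nature than the target.  Each participant contributes 2
target natures x 2 roles x 4 primes = 16 cells x 14 trials = 224 trials.

Clean response times are drawn from a condition-wise ex-Gaussian; a small
contaminant fraction is drawn uniformly outside the 250-1500 ms analysis
window (a synthetic-only device so the trimming stage has something to do).
Accuracy is Bernoulli at the cell's hit rate.  The default condition table
carries the fitted components and hit rates of the reference study, so a
simulated cohort reproduces its statistical structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exgauss import ExGaussParams

__all__ = [
    "TARGET_NATURES",
    "COUNTRIES",
    "ROLES",
    "PRIMES",
    "CONDITION_KEYS",
    "ConditionKey",
    "ConditionSpec",
    "CohortDesign",
    "ConfigurationError",
    "default_condition_table",
    "generate_cohort",
    "write_trials",
]

TARGET_NATURES = ("face", "name")
COUNTRIES = ("spain", "usa")
ROLES = ("test", "distracting")
PRIMES = ("identity", "related", "unrelated_same_nature", "unrelated_different_nature")

TRIAL_COLUMNS = [
    "participant_id",
    "country",
    "target_nature",
    "role",
    "prime",
    "rt_ms",
    "correct",
]

#: contaminant RT support, uniform on [80, 250) and (1500, 2500] ms
_CONTAM_LOW = (80.0, 250.0)
_CONTAM_HIGH = (1500.0, 2500.0)


class ConfigurationError(ValueError):
    """A design/spec mismatch, e.g. a condition cell without parameters."""


@dataclass(frozen=True)
class ConditionKey:
    """One of the 32 cells of the 2x2x2x4 design."""

    target_nature: str
    country: str
    role: str
    prime: str

    def __post_init__(self) -> None:
        if (
            self.target_nature not in TARGET_NATURES
            or self.country not in COUNTRIES
            or self.role not in ROLES
            or self.prime not in PRIMES
        ):
            raise ConfigurationError(f"unknown condition level in {self}")


#: all 32 keys, in report order (target nature, country, role, prime)
CONDITION_KEYS = tuple(
    ConditionKey(tn, co, ro, pr)
    for tn in TARGET_NATURES
    for co in COUNTRIES
    for ro in ROLES
    for pr in PRIMES
)


@dataclass(frozen=True)
class ConditionSpec:
    """Generating model of one cell: ex-Gaussian RTs plus a hit rate."""

    key: ConditionKey
    params: ExGaussParams
    hit_rate: float
    contamination_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.hit_rate <= 1.0:
            raise ConfigurationError(f"hit_rate out of [0, 1] for {self.key}")
        if not 0.0 <= self.contamination_rate <= 0.5:
            raise ConfigurationError(f"contamination_rate out of [0, 0.5] for {self.key}")


@dataclass(frozen=True)
class CohortDesign:
    """Cohort layout plus the trial-timing metadata (carried, not modelled)."""

    participants_per_country: int = 50
    trials_per_cell: int = 14
    prime_durations: Mapping[str, int] = field(
        default_factory=lambda: {
            "fixation_ms": 50,
            "prime_ms": 50,
            "mask_ms": 500,
            "target_max_ms": 500,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.participants_per_country < 1 or self.trials_per_cell < 1:
            raise ConfigurationError("participants_per_country and trials_per_cell must be >= 1")

    @property
    def cells_per_participant(self) -> int:
        # a participant sees every cell of their own country
        return len(TARGET_NATURES) * len(ROLES) * len(PRIMES)

    @property
    def trials_per_participant(self) -> int:
        return self.cells_per_participant * self.trials_per_cell


# (hit %, mu, sigma, tau) per cell, in CONDITION_KEYS order within each
# (target, country, role) block: identity, related, unrelated same nature,
# unrelated different nature.
_DEFAULT_CELLS: dict[tuple[str, str, str], tuple[tuple[int, float, float, float], ...]] = {
    ("face", "spain", "test"): (
        (81, 417.56, 18.72, 227.72),
        (83, 446.41, 17.37, 228.81),
        (83, 498.62, 77.04, 199.30),
        (78, 481.05, 61.48, 210.93),
    ),
    ("face", "spain", "distracting"): (
        (80, 468.39, 70.74, 237.74),
        (87, 502.11, 58.64, 226.07),
        (86, 483.74, 84.50, 232.73),
        (86, 520.84, 71.68, 216.90),
    ),
    ("face", "usa", "test"): (
        (71, 456.03, 56.71, 215.11),
        (76, 451.39, 36.49, 250.15),
        (73, 509.77, 54.78, 215.48),
        (69, 482.41, 44.27, 246.38),
    ),
    ("face", "usa", "distracting"): (
        (80, 463.75, 80.76, 249.63),
        (87, 498.38, 84.62, 225.55),
        (83, 469.98, 87.87, 231.21),
        (86, 509.47, 82.87, 223.49),
    ),
    ("name", "spain", "test"): (
        (79, 483.75, 67.10, 239.76),
        (80, 498.17, 63.08, 235.26),
        (80, 565.34, 96.59, 210.69),
        (80, 532.32, 80.38, 247.98),
    ),
    ("name", "spain", "distracting"): (
        (86, 582.47, 119.21, 283.59),
        (85, 615.45, 93.19, 287.98),
        (87, 614.45, 95.48, 309.80),
        (86, 563.35, 87.99, 306.72),
    ),
    ("name", "usa", "test"): (
        (78, 468.30, 60.72, 231.95),
        (77, 489.53, 72.59, 229.43),
        (78, 537.22, 57.63, 225.53),
        (78, 506.51, 67.87, 238.97),
    ),
    ("name", "usa", "distracting"): (
        (90, 502.44, 87.16, 292.10),
        (91, 555.94, 88.33, 267.74),
        (91, 547.36, 86.83, 275.37),
        (88, 517.38, 88.40, 267.42),
    ),
}


def default_condition_table(contamination_rate: float = 0.02) -> dict[ConditionKey, ConditionSpec]:
    """The 32 default cell specs: reference fitted (mu, sigma, tau) and hit rates."""
    table: dict[ConditionKey, ConditionSpec] = {}
    for (tn, co, ro), rows in _DEFAULT_CELLS.items():
        for prime, (hit, mu, sigma, tau) in zip(PRIMES, rows):
            key = ConditionKey(tn, co, ro, prime)
            table[key] = ConditionSpec(
                key=key,
                params=ExGaussParams(mu, sigma, tau),
                hit_rate=hit / 100.0,
                contamination_rate=contamination_rate,
            )
    return table


def _participant_rng(seed: int, pid: int) -> np.random.Generator:
    # deterministic per-participant substream: stable under partial regeneration
    return np.random.default_rng(np.random.SeedSequence([seed, pid]))


def _contaminant_rts(rng: np.random.Generator, n: int) -> np.ndarray:
    low_w = _CONTAM_LOW[1] - _CONTAM_LOW[0]
    high_w = _CONTAM_HIGH[1] - _CONTAM_HIGH[0]
    u = rng.uniform(0.0, low_w + high_w, n)
    return np.where(
        u < low_w,
        _CONTAM_LOW[0] + u,
        _CONTAM_HIGH[1] - (u - low_w),
    )


def generate_cohort(
    design: CohortDesign,
    specs: Mapping[ConditionKey, ConditionSpec] | None = None,
) -> pd.DataFrame:
    """Simulate one cohort; one row per trial, reproducible bit-for-bit by seed.

    Participants 0..P-1 are Spanish, P..2P-1 North American (P =
    ``participants_per_country``).  Each participant's trials are drawn from
    a dedicated RNG substream of the master seed.
    """
    if specs is None:
        specs = default_condition_table()
    P = design.participants_per_country
    frames = []
    for pid in range(2 * P):
        country = COUNTRIES[0] if pid < P else COUNTRIES[1]
        rng = _participant_rng(design.seed, pid)
        for tn in TARGET_NATURES:
            for ro in ROLES:
                for pr in PRIMES:
                    key = ConditionKey(tn, country, ro, pr)
                    try:
                        spec = specs[key]
                    except KeyError:
                        raise ConfigurationError(
                            f"no condition spec for required cell {key}"
                        ) from None
                    m = design.trials_per_cell
                    p = spec.params
                    rt = rng.normal(p.mu, p.sigma, m) + rng.exponential(p.tau, m)
                    contaminated = rng.random(m) < spec.contamination_rate
                    n_bad = int(contaminated.sum())
                    if n_bad:
                        rt[contaminated] = _contaminant_rts(rng, n_bad)
                    correct = (rng.random(m) < spec.hit_rate).astype(int)
                    frames.append(
                        pd.DataFrame(
                            {
                                "participant_id": pid,
                                "country": country,
                                "target_nature": tn,
                                "role": ro,
                                "prime": pr,
                                "rt_ms": rt,
                                "correct": correct,
                            }
                        )
                    )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the trial table as UTF-8 CSV with a header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trials.to_csv(path, index=False, encoding="utf-8")
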