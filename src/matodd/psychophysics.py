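"""Oddity-task sensitivity estimation.

An m-alternative oddity trial shows m stimuli, m-1 of which are identical
("non-targets") and one of which differs ("target"); the observer picks the
odd one.  Under the equal-variance Gaussian model each stimulus evokes an
internal response: non-targets ~ N(0, 1), target ~ N(d', 1).  The simulated
observer uses the differencing rule — it chooses the sample farthest from the
mean of the remaining samples, which is equivalent to choosing the sample
farthest from the grand mean.  Sensitivity d' is recovered from a measured
proportion correct by inverting the Monte-Carlo psychometric function.

Chance performance is 1/m: 0.25 for the four-alternative design and 1/3 for
the three-alternative design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

logger = logging.getLogger(__name__)

__all__ = [
    "OddityDesign",
    "ResponseRecord",
    "SensitivityEstimate",
    "simulate_oddity_pc",
    "simulate_oddity_trial",
    "correct_pc",
    "pc_to_dprime",
    "aggregate",
    "observer_accuracy_table",
    "cross_environment_regression",
]


@dataclass(frozen=True)
class OddityDesign:
    """Design of the oddity task: number of alternatives and simulation size."""

    m: int = 4
    n_sim: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m not in (3, 4):
            raise ValueError("m must be 3 or 4")
        if self.n_sim < 1:
            raise ValueError("n_sim must be positive")

    @property
    def chance(self) -> float:
        return 1.0 / self.m


@dataclass(frozen=True)
class ResponseRecord:
    """One observer's response on one oddity trial."""

    observer_id: str
    environment: str  # "lab" | "crowd"
    condition: "TaskCondition"
    chosen_index: int
    correct: bool


@dataclass(frozen=True)
class TaskCondition:
    """The unit at which sensitivity and feature distance are paired."""

    dimension: str  # GC | GD | OT | MP | MG | GP
    object_id: int  # 1..5
    illumination: int  # 1..3
    difficulty: float  # the target's material parameter

    def label(self) -> str:
        return f"{self.dimension}_obj{self.object_id}_ill{self.illumination}_{self.difficulty:g}"


@dataclass(frozen=True)
class SensitivityEstimate:
    pc: float
    n_trials: int
    chance: float
    d_prime: float
    sem: float | None = None  # across observers, lab mode only


def simulate_oddity_pc(d_prime: float, design: OddityDesign) -> float:
    """Monte-Carlo proportion correct of the differencing-rule oddity observer.

    Per trial, draw m-1 standard normal non-target samples and one target
    sample with mean ``d_prime``; the observer chooses the sample farthest
    from the mean of the remaining samples.  Because all samples share unit
    variance this is the sample with the largest absolute deviation from the
    grand mean.  Returns the fraction of trials where the target is chosen.
    """
    if d_prime < 0:
        raise ValueError("d_prime must be nonnegative")
    rng = np.random.default_rng(design.seed)
    n = design.n_sim
    correct = 0
    # chunked to bound memory at large n_sim
    chunk = 1_000_000
    for start in range(0, n, chunk):
        k = min(chunk, n - start)
        x = rng.standard_normal((k, design.m))
        x[:, 0] += d_prime  # target in column 0
        dev = np.abs(x - x.mean(axis=1, keepdims=True))
        correct += int(np.count_nonzero(dev.argmax(axis=1) == 0))
    return correct / n


def simulate_oddity_trial(d_prime: float, m: int, rng: np.random.Generator) -> bool:
    """One simulated oddity trial; True if the target is chosen."""
    x = rng.standard_normal(m)
    x[0] += d_prime
    dev = np.abs(x - x.mean())
    return int(dev.argmax()) == 0


def correct_pc(pc: float, n_trials: int) -> float:
    """Cap a perfect proportion at 1 - 1/(2N) to keep d' finite.

    Proportions below the cap pass through unchanged.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    if not (0.0 <= pc <= 1.0):
        raise ValueError("pc must lie in [0, 1]")
    return min(pc, 1.0 - 1.0 / (2.0 * n_trials))


class _PsychometricLookup:
    """Monotone interpolation of the simulated psychometric function.

    simulate_oddity_pc is evaluated once per (m, n_sim, seed) on a fixed d'
    grid; a shape-preserving (PCHIP) interpolant maps d' -> pc, inverted by
    bisection.  The raw Monte-Carlo curve is enforced monotone by a running
    maximum before interpolation (Monte-Carlo jitter is far below the grid's
    pc increments at the default n_sim).
    """

    _cache: dict[tuple[int, int, int], "_PsychometricLookup"] = {}

    #: d' grid: dense at low sensitivity where the curve is steepest.
    GRID = np.concatenate([np.linspace(0.0, 2.0, 21), np.linspace(2.2, 8.0, 30)])

    def __init__(self, design: OddityDesign) -> None:
        pcs = np.array([simulate_oddity_pc(d, design) for d in self.GRID])
        pcs = np.maximum.accumulate(pcs)
        # strictly increasing knots required by the interpolator
        keep = np.concatenate([[True], np.diff(pcs) > 0])
        self._dgrid = self.GRID[keep]
        self._pcs = pcs[keep]
        self._interp = PchipInterpolator(self._dgrid, self._pcs)
        self._chance = design.chance

    @classmethod
    def for_design(cls, design: OddityDesign) -> "_PsychometricLookup":
        key = (design.m, design.n_sim, design.seed)
        if key not in cls._cache:
            cls._cache[key] = cls(design)
        return cls._cache[key]

    def invert(self, pc: float) -> float:
        if pc <= self._pcs[0] or pc <= self._chance:
            return 0.0
        if pc >= self._pcs[-1]:
            return float(self._dgrid[-1])
        lo, hi = float(self._dgrid[0]), float(self._dgrid[-1])
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if float(self._interp(mid)) < pc:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


def pc_to_dprime(
    pc: float, design: OddityDesign, n_trials: int
) -> SensitivityEstimate:
    """Convert a proportion correct to a sensitivity estimate.

    Applies the finite-trial ceiling correction, then inverts the simulated
    psychometric function.  Proportions at or below chance floor at d' = 0.
    """
    pc_corr = correct_pc(pc, n_trials)
    lookup = _PsychometricLookup.for_design(design)
    d = lookup.invert(pc_corr)
    return SensitivityEstimate(
        pc=pc_corr, n_trials=n_trials, chance=design.chance, d_prime=d
    )


def _design_for(records: list[ResponseRecord], n_sim: int, seed: int) -> OddityDesign:
    m = 4 if records[0].condition.illumination == 1 else 3
    return OddityDesign(m=m, n_sim=n_sim, seed=seed)


def aggregate(
    records: list[ResponseRecord],
    mode: str = "pooled",
    n_sim: int = 200_000,
    seed: int = 0,
) -> dict[TaskCondition, SensitivityEstimate]:
    """Aggregate trial records into per-condition sensitivity estimates.

    mode="per_observer" (laboratory convention): estimate d' separately per
    observer from that observer's proportion correct, then report the mean
    across observers with its SEM (sample SD / sqrt(n_observers)).

    mode="pooled" (crowdsourcing convention, one trial per observer): pool
    all responses into a single proportion correct, then one d'.
    """
    if mode not in ("pooled", "per_observer"):
        raise ValueError(f"unknown mode {mode!r}")
    if not records:
        raise ValueError("no records supplied")
    by_cond: dict[TaskCondition, list[ResponseRecord]] = {}
    for r in records:
        by_cond.setdefault(r.condition, []).append(r)

    out: dict[TaskCondition, SensitivityEstimate] = {}
    for cond, recs in by_cond.items():
        if not recs:
            warnings.warn(f"condition {cond.label()} has no responses; omitted")
            continue
        design = _design_for(recs, n_sim, seed)
        if mode == "pooled":
            pc = float(np.mean([r.correct for r in recs]))
            out[cond] = pc_to_dprime(pc, design, n_trials=len(recs))
        else:
            per_obs: dict[str, list[bool]] = {}
            for r in recs:
                per_obs.setdefault(r.observer_id, []).append(r.correct)
            dprimes = []
            for obs, answers in per_obs.items():
                pc = float(np.mean(answers))
                dprimes.append(
                    pc_to_dprime(pc, design, n_trials=len(answers)).d_prime
                )
            dprimes = np.asarray(dprimes)
            pc_all = float(np.mean([r.correct for r in recs]))
            sem = (
                float(dprimes.std(ddof=1) / np.sqrt(len(dprimes)))
                if len(dprimes) > 1
                else None
            )
            out[cond] = SensitivityEstimate(
                pc=pc_all,
                n_trials=len(recs),
                chance=design.chance,
                d_prime=float(dprimes.mean()),
                sem=sem,
            )
    return out


def observer_accuracy_table(records: list[ResponseRecord]) -> pd.DataFrame:
    """Per-observer accuracy averaged across objects and task difficulties.

    Returns one row per (observer, environment, dimension, illumination) with
    the observer's mean proportion correct — the quantity whose histogram and
    SD summarize individual differences.
    """
    rows = [
        {
            "observer_id": r.observer_id,
            "environment": r.environment,
            "dimension": r.condition.dimension,
            "illumination": r.condition.illumination,
            "correct": float(r.correct),
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    return (
        df.groupby(["observer_id", "environment", "dimension", "illumination"])[
            "correct"
        ]
        .mean()
        .rename("accuracy")
        .reset_index()
    )


@dataclass(frozen=True)
class RegressionLine:
    slope: float
    intercept: float
    r_squared: float


def cross_environment_regression(
    x: np.ndarray, y: np.ndarray
) -> RegressionLine:
    """OLS of crowd d' (y) on lab d' (x), with intercept.

    Used to quantify how well sensitivity transfers between controlled
    laboratory viewing and uncontrolled crowdsourced viewing; a slope below
    one indicates attenuated crowd sensitivity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired estimates")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("estimates must be finite")
    res = stats.linregress(x, y)
    return RegressionLine(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
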