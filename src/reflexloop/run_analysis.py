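"""Aggregate trial measurements into recruitment curves, response-size
distributions, operant-conditioning criteria, and reference-stability
reports.

Conventions (declared, so thresholds are bit-reproducible):

* percentiles use linear interpolation between order statistics
  (numpy's "linear" method);
* a trial whose size ties the criterion threshold counts as a success;
* down-conditioning succeeds when size <= threshold at the P-th
  percentile; up-conditioning succeeds when size >= the (100 - P)-th
  percentile, so in both directions the criterion admits the "easiest"
  P percent of the defining sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .response_analysis import METHOD_P2P

#: Protocol default target percentile for conditioning criteria.
DEFAULT_TARGET_PERCENTILE = 66.0

#: Protocol default pooling group size for recruitment-curve sweeps
#: (intensity stepped every four trials).
DEFAULT_POOL_SIZE = 4

#: Default tolerance on M-wave constancy, fraction of nominal.
DEFAULT_STABILITY_TOLERANCE = 0.15

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"


def pool_trials(sizes: Sequence[float], k: int) -> np.ndarray:
    """Means of consecutive groups of k trials, in order.

    The final group may be smaller; it is averaged over its actual size.
    """
    if k < 1:
        raise ValueError("pool size k must be >= 1")
    sizes = np.asarray(sizes, dtype=float)
    if sizes.ndim != 1:
        raise ValueError("sizes must be 1-D")
    return np.array([sizes[i : i + k].mean() for i in range(0, sizes.size, k)])


@dataclass
class RecruitmentCurve:
    """Pooled stimulus-response relationship with its extrema.

    ``points`` columns: intensity_mA (or pooled-group index when no
    schedule is known), reference_size, target_size, n.
    """

    points: pd.DataFrame
    pool_size: int
    m_max: float
    h_max: float
    method: str = METHOD_P2P


def build_recruitment_curve(
    trials: pd.DataFrame,
    intensity_schedule: Optional[Sequence[float]] = None,
    pool_size: int = DEFAULT_POOL_SIZE,
    method: str = METHOD_P2P,
) -> RecruitmentCurve:
    """Pool a recruitment-sweep trial table and extract M_max / H_max.

    ``intensity_schedule`` may give one intensity per trial or one per
    pooled group; if its length matches neither, pooled-group indices are
    used instead (with a warning).  When the trial table itself carries
    intensities they are used as a per-trial schedule by default.
    """
    if len(trials) < pool_size:
        raise ValueError("fewer trials than one pooling group")
    ref = pool_trials(trials["reference_size"].to_numpy(), pool_size)
    tgt = pool_trials(trials["target_size"].to_numpy(), pool_size)
    n_groups = ref.size
    counts = np.full(n_groups, pool_size)
    counts[-1] = len(trials) - pool_size * (n_groups - 1)

    if intensity_schedule is None and trials["intensity_mA"].notna().all():
        intensity_schedule = trials["intensity_mA"].to_numpy()
    if intensity_schedule is not None:
        sched = np.asarray(intensity_schedule, dtype=float)
        if sched.size == len(trials):
            intensity = pool_trials(sched, pool_size)
        elif sched.size == n_groups:
            intensity = sched
        else:
            warnings.warn(
                "intensity schedule length matches neither trials nor "
                "pooled groups; falling back to group index",
                stacklevel=2,
            )
            intensity = np.arange(1, n_groups + 1, dtype=float)
    else:
        intensity = np.arange(1, n_groups + 1, dtype=float)

    points = pd.DataFrame(
        {
            "intensity_mA": intensity,
            "reference_size": ref,
            "target_size": tgt,
            "n": counts,
        }
    )
    return RecruitmentCurve(
        points=points,
        pool_size=pool_size,
        m_max=float(ref.max()),
        h_max=float(tgt.max()),
        method=method,
    )


@dataclass
class ResponseDistribution:
    """Sample of target response sizes with summary statistics."""

    sizes: np.ndarray
    target_percentile: float = DEFAULT_TARGET_PERCENTILE

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.size == 0:
            raise ValueError("empty response-size sample")

    @property
    def count(self) -> int:
        return int(self.sizes.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.sizes))

    @property
    def median(self) -> float:
        return float(np.median(self.sizes))

    def percentile(self, p: float) -> float:
        return float(np.percentile(self.sizes, p, method="linear"))

    @property
    def down_criterion_level(self) -> float:
        return self.percentile(self.target_percentile)

    @property
    def up_criterion_level(self) -> float:
        return self.percentile(100.0 - self.target_percentile)

    def summary(self) -> dict:
        return {
            "count": self.count,
            "mean": self.mean,
            "median": self.median,
            "target_percentile": self.target_percentile,
            "down_criterion": self.down_criterion_level,
            "up_criterion": self.up_criterion_level,
        }


def compute_distribution(
    sizes: Sequence[float], target_percentile: float = DEFAULT_TARGET_PERCENTILE
) -> ResponseDistribution:
    """Distribution of target response sizes with criterion lines."""
    return ResponseDistribution(np.asarray(sizes, dtype=float), target_percentile)


@dataclass(frozen=True)
class ConditioningCriterion:
    """Success rule for operant conditioning: direction plus threshold."""

    direction: str
    threshold: float
    target_percentile: float

    def __post_init__(self) -> None:
        if self.direction not in (DIRECTION_UP, DIRECTION_DOWN):
            raise ValueError("direction must be 'up' or 'down'")


def criterion_from_distribution(
    dist: ResponseDistribution | Sequence[float],
    percentile: float = DEFAULT_TARGET_PERCENTILE,
    direction: str = DIRECTION_DOWN,
) -> ConditioningCriterion:
    """Derive a conditioning criterion from a measured distribution.

    Down-conditioning: success means a size in the bottom P percent, so
    the threshold is the P-th percentile.  Up-conditioning: success means
    a size in the top P percent, so the threshold is the (100 - P)-th
    percentile.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    if not isinstance(dist, ResponseDistribution):
        dist = compute_distribution(dist, percentile)
    if direction == DIRECTION_DOWN:
        threshold = dist.percentile(percentile)
    elif direction == DIRECTION_UP:
        threshold = dist.percentile(100.0 - percentile)
    else:
        raise ValueError("direction must be 'up' or 'down'")
    return ConditioningCriterion(
        direction=direction, threshold=threshold, target_percentile=percentile
    )


def classify_trial(size: float, criterion: ConditioningCriterion) -> bool:
    """Success flag for one trial; ties at the threshold count as success."""
    if criterion.direction == DIRECTION_DOWN:
        return size <= criterion.threshold
    return size >= criterion.threshold


def success_rate(outcomes: Sequence[bool]) -> np.ndarray:
    """Running cumulative success percentage after each trial.

    Empty input yields an empty array (the display shows blank before the
    first trial).
    """
    outcomes = np.asarray(outcomes, dtype=bool)
    if outcomes.size == 0:
        return np.array([])
    return 100.0 * np.cumsum(outcomes) / np.arange(1, outcomes.size + 1)


@dataclass
class StabilityReport:
    """Retrospective check that the reference (M-wave) stayed constant."""

    nominal_reference: float
    run_mean: float
    deviations: np.ndarray  # per-trial (size - nominal) / nominal
    tolerance: float
    flagged: bool


def assess_reference_stability(
    reference_sizes: Sequence[float],
    nominal: float,
    tolerance: float = DEFAULT_STABILITY_TOLERANCE,
) -> StabilityReport:
    """Flag a run whose mean M-wave drifts beyond tolerance of nominal.

    A roughly constant M-wave indicates constant effective stimulation of
    the nerve, which is the precondition for interpreting target-response
    changes as conditioning effects.
    """
    sizes = np.asarray(reference_sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("no reference sizes to assess")
    if nominal <= 0:
        raise ValueError("nominal reference size must be positive")
    run_mean = float(sizes.mean())
    deviations = (sizes - nominal) / nominal
    flagged = abs(run_mean - nominal) > tolerance * nominal
    return StabilityReport(
        nominal_reference=float(nominal),
        run_mean=run_mean,
        deviations=deviations,
        tolerance=float(tolerance),
        flagged=bool(flagged),
    )


# --------------------------------------------------------------------------
# Display helpers (never used in computation)


def histogram_bins(sizes: Sequence[float]) -> np.ndarray:
    """Freedman-Diaconis-style automatic bin edges for display."""
    return np.histogram_bin_edges(np.asarray(sizes, dtype=float), bins="fd")


def plot_recruitment_curve(curve: RecruitmentCurve, ax=None):
    """Pooled reference/target sizes versus stimulus intensity."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = curve.points
    ax.plot(pts["intensity_mA"], pts["reference_size"], "^-", label="reference (M)")
    ax.plot(pts["intensity_mA"], pts["target_size"], "o-", label="target (H)")
    ax.set_xlabel("stimulus intensity (mA)")
    ax.set_ylabel(f"response size (mV, {curve.method})")
    ax.legend()
    return ax


def plot_distribution(dist: ResponseDistribution, ax=None):
    """Histogram of target sizes with median and criterion lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.hist(dist.sizes, bins=histogram_bins(dist.sizes))
    for label, x in (
        ("median", dist.median),
        ("down criterion", dist.down_criterion_level),
        ("up criterion", dist.up_criterion_level),
    ):
        ax.axvline(x, color="red", linestyle="--", alpha=0.7)
        ax.annotate(label, (x, ax.get_ylim()[1]), rotation=90, fontsize=7)
    ax.set_xlabel("target response size (mV)")
    ax.set_ylabel("trials")
    return ax
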