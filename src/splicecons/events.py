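"""Percentile-threshold splice-event calling and per-group count summaries.

An exon-sample cell is called an event when its FIRMA score falls outside
global thresholds set at the 1st and 99th percentiles of the pooled scores of
all exons in all samples.  Scores above the upper threshold are *inclusion*
calls, scores below the lower threshold are *exclusion* (skipping) calls;
inequalities are strict, so inclusion, exclusion and uncalled cells partition
the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, ValidationError
from .firma import FirmaScoreMatrix

__all__ = [
    "ThresholdPair",
    "EventCallSet",
    "EventCountSummary",
    "compute_thresholds",
    "call_events",
    "summarize_event_counts",
]

INCLUSION = "inclusion"
EXCLUSION = "exclusion"
DIRECTIONS = (INCLUSION, EXCLUSION)


@dataclass(frozen=True)
class ThresholdPair:
    """Global score thresholds: exclusion below q_low, inclusion above q_high."""

    q_low: float
    q_high: float
    lower_pct: float = 1.0
    upper_pct: float = 99.0

    def __post_init__(self) -> None:
        if self.q_low > self.q_high:
            raise ValidationError("q_low must be <= q_high")


@dataclass
class EventCallSet:
    """All events called in one sample.

    ``events`` maps (transcript_id, exon_id, direction) to the FIRMA score
    that triggered the call; an (exon, sample) pair carries at most one
    direction because the thresholds are disjoint.
    """

    sample_id: str
    events: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def keys(self, direction: str | None = None) -> set[tuple[str, str, str]]:
        if direction is None:
            return set(self.events)
        return {k for k in self.events if k[2] == direction}

    def count(self, direction: str) -> int:
        return sum(1 for k in self.events if k[2] == direction)


@dataclass
class EventCountSummary:
    """Per-group event-count summary: median with a bootstrap 95% CI."""

    group: str
    direction: str
    counts: list[int]
    median: float
    ci_low: float
    ci_high: float
    p_value: float  # across-group rank-test p, shared by all groups

    def __post_init__(self) -> None:
        if not self.ci_low <= self.median <= self.ci_high:
            raise ValidationError("CI must bracket the median")


def compute_thresholds(
    scores: FirmaScoreMatrix, lower_pct: float = 1.0, upper_pct: float = 99.0
) -> ThresholdPair:
    """Percentiles of the pooled exon-by-sample scores, all groups together.

    Uses linear interpolation between closest order statistics (the numpy
    default convention).  Raises if the scores carry no spread.
    """
    if not 0 <= lower_pct < upper_pct <= 100:
        raise ValidationError("need 0 <= lower_pct < upper_pct <= 100")
    pooled = scores.pooled()
    if pooled.size < 2 or np.all(pooled == pooled[0]):
        raise DegenerateDataError(
            "all scores identical: percentile thresholds are degenerate"
        )
    q_low, q_high = np.percentile(pooled, [lower_pct, upper_pct])
    return ThresholdPair(float(q_low), float(q_high), lower_pct, upper_pct)


def call_events(
    scores: FirmaScoreMatrix, thr: ThresholdPair
) -> list[EventCallSet]:
    """Call events per sample with strict threshold inequalities.

    score > q_high -> inclusion; score < q_low -> exclusion; ties at either
    threshold remain uncalled.
    """
    callsets = []
    mat = scores.scores
    vals = mat.to_numpy()
    index = mat.index
    for j, sample_id in enumerate(mat.columns):
        col = vals[:, j]
        events: dict[tuple[str, str, str], float] = {}
        for i in np.flatnonzero(col > thr.q_high):
            t, e = index[i]
            events[(t, e, INCLUSION)] = float(col[i])
        for i in np.flatnonzero(col < thr.q_low):
            t, e = index[i]
            events[(t, e, EXCLUSION)] = float(col[i])
        callsets.append(EventCallSet(str(sample_id), events))
    return callsets


def _bootstrap_median_ci(
    counts: np.ndarray, B: int, rng: np.random.Generator, level: float = 0.95
) -> tuple[float, float]:
    n = counts.size
    idx = rng.integers(0, n, size=(B, n))
    meds = np.median(counts[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(meds, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def summarize_event_counts(
    callsets: list[EventCallSet],
    sample_groups: pd.Series,
    direction: str,
    B: int = 2000,
    seed: int | None = None,
) -> list[EventCountSummary]:
    """Median per-sample event counts per group, with bootstrap 95% CIs.

    The across-group comparison is a two-sided rank test: Mann-Whitney for
    two groups, Kruskal-Wallis for three or more; its p-value is attached to
    every group's summary.
    """
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}")
    unknown = [cs.sample_id for cs in callsets if cs.sample_id not in sample_groups.index]
    if unknown:
        raise ValidationError(f"samples missing from group map: {unknown!r}")
    rng = np.random.default_rng(seed)

    by_group: dict[str, list[int]] = {}
    for cs in callsets:
        by_group.setdefault(str(sample_groups[cs.sample_id]), []).append(
            cs.count(direction)
        )
    for g, counts in by_group.items():
        if len(counts) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")

    groups_sorted = sorted(by_group)
    arrays = [np.asarray(by_group[g], dtype=float) for g in groups_sorted]
    pooled = np.concatenate(arrays)
    if len(arrays) == 1:
        p_value = float("nan")
    elif np.all(pooled == pooled[0]):
        p_value = 1.0  # every count identical: no rank information at all
    elif len(arrays) == 2:
        p_value = float(
            stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided").pvalue
        )
    else:
        p_value = float(stats.kruskal(*arrays).pvalue)

    out = []
    for g, arr in zip(groups_sorted, arrays):
        lo, hi = _bootstrap_median_ci(arr, B, rng)
        out.append(
            EventCountSummary(
                group=g,
                direction=direction,
                counts=[int(c) for c in arr],
                median=float(np.median(arr)),
                ci_low=lo,
                ci_high=hi,
                p_value=p_value,
            )
        )
    return out
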