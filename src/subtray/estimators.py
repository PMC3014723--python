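"""Abundance and richness estimation from the three-phase protocol.

The abundance estimator is the fixed-area plug-in: the mean count per counted
cell, multiplied by the plate's total area in cell-equivalents (63.6 for the
standard tray), estimates the on-tray (phase-2) abundance; the exhaustively
counted large-specimen pool is added on top for the whole-sample estimate.

Percent accuracy scores the phase-2 estimate against the true on-tray count
(total minus the sieve pool): 100 means exact, values below/above 100 are
under-/over-estimates. Taxa richness is the union of taxa recorded by all
three phases.

The full-count decision rule: if after counting 10 cells the mean count per
cell is below 4, the sample is sparse enough (roughly < 250 individuals) that
extrapolation is unreliable and counting the whole sample is recommended.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .protocol import ProtocolResult

__all__ = [
    "AbundanceEstimate",
    "AbundanceCategory",
    "estimate_phase2",
    "estimate_abundance",
    "percent_accuracy",
    "total_percent_accuracy",
    "taxa_richness",
    "percent_richness",
    "classify_abundance",
    "recommend_full_count",
    "FULL_COUNT_MEAN_THRESHOLD",
    "FULL_COUNT_K",
]

#: Full-count rule: recommend counting everything when the mean per cell,
#: computed after exactly FULL_COUNT_K cells, is below this threshold.
FULL_COUNT_MEAN_THRESHOLD = 4.0
FULL_COUNT_K = 10


@dataclass(frozen=True)
class AbundanceEstimate:
    """A plug-in abundance estimate and its components."""

    mean_per_cell: float
    phase2_estimate: float
    large_count: int
    k_used: int

    @property
    def total_estimate(self) -> float:
        return self.phase2_estimate + self.large_count


class AbundanceCategory(str, enum.Enum):
    """Sample-size category by true total abundance."""

    LOW = "low"            # < 250 individuals
    MODERATE = "moderate"  # 250-500 individuals
    HIGH = "high"          # > 500 individuals

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def estimate_phase2(observed_counts, k: int,
                    equivalent_cells: float = 63.6,
                    large_count: int = 0) -> AbundanceEstimate:
    """Extrapolate counted-cell totals to the whole tray.

    Parameters
    ----------
    observed_counts : array-like or scalar
        Counts recorded in the k counted cells (any shape; summed).
    k : int
        Number of cells counted.
    equivalent_cells : float
        The tray's area in cell units (the extrapolation multiplier).
    large_count : int
        Phase-1 sieve count, carried into ``total_estimate``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    total = float(np.sum(observed_counts))
    if total < 0:
        raise ValueError("observed counts must be non-negative")
    mean_per_cell = total / k
    return AbundanceEstimate(mean_per_cell=mean_per_cell,
                             phase2_estimate=mean_per_cell * equivalent_cells,
                             large_count=int(large_count), k_used=k)


def estimate_abundance(result: ProtocolResult,
                       equivalent_cells: float = 63.6,
                       k: int | None = None) -> AbundanceEstimate:
    """Estimate from a full protocol result, optionally at a nested k."""
    sub = result.subsample if k is None else result.subsample.prefix(k)
    return estimate_phase2(sub.observed_counts, sub.k, equivalent_cells,
                           large_count=int(result.large_counts.sum()))


def percent_accuracy(phase2_estimate: float, true_phase2_total: float) -> float:
    """Accuracy of the extrapolated on-tray estimate, in percent.

    Defined on the phase-2 portion only: the divisor is the true sample count
    minus the large specimens removed in phase 1. Under 100 = underestimate,
    over 100 = overestimate.
    """
    if true_phase2_total <= 0:
        raise ValueError(
            "percent accuracy undefined for empty phase-2 truth; "
            "filter such samples out")
    return 100.0 * phase2_estimate / true_phase2_total


def total_percent_accuracy(estimate: AbundanceEstimate,
                           true_total: float) -> float:
    """Convenience variant scoring the whole-sample estimate (phase-2
    extrapolation plus large pool) against the full true total. Not part of
    the published accuracy statistic, which is phase-2 only."""
    if true_total <= 0:
        raise ValueError("true_total must be positive")
    return 100.0 * estimate.total_estimate / true_total


def taxa_richness(result: ProtocolResult) -> int:
    """Number of distinct taxa recorded across all three phases."""
    return len(result.detected_taxa)


def percent_richness(detected: int, true_richness: int) -> float:
    """Detected richness as a percentage of the true richness."""
    if true_richness <= 0:
        raise ValueError("percent richness undefined for zero true richness")
    if not 0 <= detected <= true_richness:
        raise ValueError("detected must be in [0, true_richness]")
    return 100.0 * detected / true_richness


def classify_abundance(true_total: int) -> AbundanceCategory:
    """Size category of a sample by its total count.

    Boundaries are closed into the moderate class: < 250 low, 250-500
    moderate, > 500 high.
    """
    if true_total < 0:
        raise ValueError("true_total must be non-negative")
    if true_total < 250:
        return AbundanceCategory.LOW
    if true_total <= 500:
        return AbundanceCategory.MODERATE
    return AbundanceCategory.HIGH


def recommend_full_count(mean_per_cell: float) -> bool:
    """Whether to abandon subsampling and count the entire sample.

    ``mean_per_cell`` must come from exactly 10 counted cells. True
    (full count) iff the mean is strictly below 4 per cell; a mean of
    exactly 4 proceeds with estimation.
    """
    if mean_per_cell < 0:
        raise ValueError("mean_per_cell must be non-negative")
    return mean_per_cell < FULL_COUNT_MEAN_THRESHOLD
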