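"""The three-phase laboratory sorting protocol.

Phase 1 — sieve: large specimens retained on a 4 mm mesh are counted and
identified exhaustively (assumed lossless).

Phase 2 — subsample: k distinct complete cells are drawn uniformly without
replacement (the pooled edge region is never selectable) and every individual
in a selected cell is seen independently with its taxon's in-cell detection
probability. Missed individuals stay on the tray.

Phase 3 — quick scan: the remaining material is scanned for taxa not yet
seen. A taxon with m undetected individuals left anywhere on the tray
(unselected cells, edge region, or missed inside counted cells) is noticed
with probability 1 - (1 - q)^m, where q is its per-individual scan
probability. The scan records presence only; it contributes to taxa richness,
never to abundance.

The phase-2 cell selection is kept in draw order so that nested prefixes
(the first k' < k cells of one selection) reproduce what a technician who
stopped early would have recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import SampleRealization

__all__ = [
    "SubsampleResult",
    "ProtocolResult",
    "phase1_sieve",
    "phase2_subsample",
    "phase3_scan",
    "run_protocol",
]


@dataclass
class SubsampleResult:
    """What phase 2 recorded: which cells, in order, and what was seen."""

    selected_cells: np.ndarray  # ordered, 0-based complete-cell indices
    observed_counts: np.ndarray  # (k, n_taxa), in selection order
    k: int

    def __post_init__(self) -> None:
        if len(self.selected_cells) != self.k:
            raise ValueError("selected_cells length must equal k")
        if len(np.unique(self.selected_cells)) != self.k:
            raise ValueError("selected cells must be distinct")
        if (self.observed_counts < 0).any():
            raise ValueError("observed counts must be non-negative")

    @property
    def observed_total(self) -> int:
        return int(self.observed_counts.sum())

    def prefix(self, k: int) -> "SubsampleResult":
        """The result had the technician stopped after the first ``k`` cells."""
        if not 1 <= k <= self.k:
            raise ValueError(f"prefix k must be in [1, {self.k}]")
        return SubsampleResult(selected_cells=self.selected_cells[:k],
                               observed_counts=self.observed_counts[:k],
                               k=k)


@dataclass
class ProtocolResult:
    """Everything the three phases recorded for one sample."""

    taxon_ids: tuple[str, ...]
    large_counts: np.ndarray  # per taxon, phase 1
    subsample: SubsampleResult  # phase 2
    scan_taxa: frozenset[str]  # phase 3: taxa first seen during the scan
    k_used: int

    def __post_init__(self) -> None:
        if self.scan_taxa & self.detected_taxa_phase12:
            raise ValueError("scan_taxa must be disjoint from phases 1-2")

    @property
    def detected_taxa_phase12(self) -> frozenset[str]:
        ids = np.asarray(self.taxon_ids)
        seen = (self.large_counts > 0) | \
               (self.subsample.observed_counts.sum(axis=0) > 0)
        return frozenset(ids[seen])

    @property
    def detected_taxa(self) -> frozenset[str]:
        return self.detected_taxa_phase12 | self.scan_taxa


def phase1_sieve(sample: SampleRealization) -> np.ndarray:
    """Per-taxon counts of sieve-retained large specimens (lossless)."""
    return sample.large_counts.copy()


def phase2_subsample(sample: SampleRealization, k: int,
                     rng: np.random.Generator) -> SubsampleResult:
    """Count ``k`` randomly selected complete cells with imperfect detection.

    Cells are drawn uniformly without replacement from the complete cells
    only. Observation is a per-individual Bernoulli thinning with each
    taxon's ``p_detect_cell``, so observed counts can never exceed the truth.
    """
    C = sample.geometry.n_complete_cells
    if not 1 <= k <= C:
        raise ValueError(f"k must be in [1, {C}], got {k}")
    cells = rng.choice(C, size=k, replace=False)
    p = np.array([t.p_detect_cell for t in sample.taxa])
    truth = sample.cell_counts[cells]
    observed = rng.binomial(truth, p)
    return SubsampleResult(selected_cells=cells, observed_counts=observed, k=k)


def phase3_scan(sample: SampleRealization,
                detected_so_far: frozenset[str] | set[str],
                rng: np.random.Generator,
                observed_counts_by_taxon: np.ndarray | None = None,
                ) -> frozenset[str]:
    """Quick scan of the tray remainder for taxa not yet detected.

    For each undetected taxon, m is the number of its individuals still on
    the tray (everything outside the large pool that phase 2 did not record;
    phase-2 misses remain physically present and thus scannable). Detection
    probability is 1 - (1 - q)^m. Returns the set of newly seen taxa —
    presence only.
    """
    small = sample.small_totals
    if observed_counts_by_taxon is None:
        observed_counts_by_taxon = np.zeros_like(small)
    remaining = small - np.asarray(observed_counts_by_taxon)
    if (remaining < 0).any():
        raise ValueError("observed counts exceed tray totals")
    found = []
    for t, m in zip(sample.taxa, remaining):
        if t.taxon_id in detected_so_far or m <= 0:
            continue
        p_detect = 1.0 - (1.0 - t.p_detect_scan_per_individual) ** int(m)
        if rng.random() < p_detect:
            found.append(t.taxon_id)
    return frozenset(found)


def run_protocol(sample: SampleRealization, k: int = 16,
                 rng: np.random.Generator | None = None) -> ProtocolResult:
    """Run the three phases in order on one ground-truth sample.

    The ordered phase-2 selection is retained so estimates for any k' <= k
    can be read off the nested prefix.
    """
    if rng is None:
        rng = np.random.default_rng()
    large = phase1_sieve(sample)
    sub = phase2_subsample(sample, k, rng)
    ids = np.asarray(sample.taxon_ids)
    observed_by_taxon = sub.observed_counts.sum(axis=0)
    detected = frozenset(ids[(large > 0) | (observed_by_taxon > 0)])
    scan = phase3_scan(sample, detected, rng, observed_by_taxon)
    return ProtocolResult(taxon_ids=sample.taxon_ids, large_counts=large,
                          subsample=sub, scan_taxa=scan, k_used=k)
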