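"""Synthetic invertebrate communities and ground-truth tray samples.

Emulates the statistical structure of pan- and pitfall-trap samples: sample
totals spanning roughly 90–5,300 individuals, long-tailed (lognormal)
rank-abundance structure with a handful of common taxa and many rare ones, a
"large specimen" fraction retained on a 4 mm sieve, and taxon-specific
detection probabilities for small, pale taxa that are hard to see against a
white tray.

A ground-truth :class:`SampleRealization` records, per taxon, the counts in
each complete grid cell, in the pooled edge region, and in the large-specimen
pool, so that every downstream protocol phase and estimator can be checked
against exact truth.

Spatial placement is multinomial over regions weighted by area (the "evenly
brushed" tray). A Dirichlet-multinomial clustered mode is provided as a
sensitivity knob for probing the estimator's behaviour when dispersal is
imperfect; ``clustering_theta = inf`` recovers the uniform case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import NormalDist
from typing import Sequence

import numpy as np

from .geometry import TrayGeometry

__all__ = [
    "TaxonSpec",
    "CommunityConfig",
    "SampleRealization",
    "draw_community",
    "split_large",
    "allocate_to_tray",
    "draw_sample",
    "lognormal_weights",
    "preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class TaxonSpec:
    """Per-taxon parameters of the synthetic community.

    Parameters
    ----------
    taxon_id : str
        Short label, typically an order or family name.
    relative_abundance : float
        Positive weight; individuals are allocated to taxa proportionally.
    large_fraction : float
        Probability that an individual is retained by the 4 mm sieve
        (phase 1).
    p_detect_cell : float
        Probability that an individual sitting in a counted cell is seen
        during phase 2. Below 1 for small, pale taxa.
    p_detect_scan_per_individual : float
        Probability that any single remaining individual of the taxon is
        noticed during the phase-3 quick scan.
    """

    taxon_id: str
    relative_abundance: float
    large_fraction: float = 0.0
    p_detect_cell: float = 1.0
    p_detect_scan_per_individual: float = 0.5

    def __post_init__(self) -> None:
        if self.relative_abundance <= 0:
            raise ValueError(f"{self.taxon_id}: relative_abundance must be > 0")
        for name in ("large_fraction", "p_detect_cell",
                     "p_detect_scan_per_individual"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.taxon_id}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class CommunityConfig:
    """A synthetic community plus the sampling distribution of its totals.

    ``total_abundance`` is a named distribution tuple: ``("fixed", n)`` or
    ``("loguniform", lo, hi)`` (inclusive integer range, log-uniform because
    trap totals span more than an order of magnitude).

    ``clustering_theta`` is the Dirichlet concentration of spatial clumping:
    ``math.inf`` means perfectly even dispersal; smaller values mean stronger
    clumping (more overdispersed cell counts).
    """

    taxa: tuple[TaxonSpec, ...]
    total_abundance: tuple = ("loguniform", 100, 1000)
    clustering_theta: float = math.inf
    rng_seed: int | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.taxa) == 0:
            raise ValueError("community needs at least one taxon")
        if not self.clustering_theta > 0:
            raise ValueError("clustering_theta must be positive")
        kind = self.total_abundance[0]
        if kind == "fixed":
            if self.total_abundance[1] < 0:
                raise ValueError("fixed total must be non-negative")
        elif kind == "loguniform":
            _, lo, hi = self.total_abundance
            if not (0 < lo <= hi):
                raise ValueError("loguniform range needs 0 < lo <= hi")
        else:
            raise ValueError(f"unknown total_abundance kind {kind!r}")

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return tuple(t.taxon_id for t in self.taxa)

    @property
    def weights(self) -> np.ndarray:
        w = np.array([t.relative_abundance for t in self.taxa], dtype=float)
        return w / w.sum()

    def draw_total(self, rng: np.random.Generator) -> int:
        kind = self.total_abundance[0]
        if kind == "fixed":
            return int(self.total_abundance[1])
        _, lo, hi = self.total_abundance
        return int(math.floor(math.exp(rng.uniform(math.log(lo),
                                                   math.log(hi + 1)))))


@dataclass
class SampleRealization:
    """Ground truth for one tray sample.

    ``cell_counts`` has one row per complete cell plus a final row for the
    pooled edge region, one column per taxon. ``large_counts`` is the per-taxon
    sieve-retained pool (never on the tray).
    """

    taxa: tuple[TaxonSpec, ...]
    geometry: TrayGeometry
    cell_counts: np.ndarray  # (n_complete_cells + 1, n_taxa) int
    large_counts: np.ndarray  # (n_taxa,) int

    def __post_init__(self) -> None:
        C = self.geometry.n_complete_cells
        if self.cell_counts.shape != (C + 1, len(self.taxa)):
            raise ValueError("cell_counts shape mismatch with geometry/taxa")
        if (self.cell_counts < 0).any() or (self.large_counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return tuple(t.taxon_id for t in self.taxa)

    @property
    def small_totals(self) -> np.ndarray:
        """Per-taxon individuals on the tray (complete cells + edge)."""
        return self.cell_counts.sum(axis=0)

    @property
    def true_total(self) -> int:
        return int(self.cell_counts.sum() + self.large_counts.sum())

    @property
    def true_phase2_total(self) -> int:
        """Individuals subject to subsampling: total minus the sieve pool."""
        return int(self.cell_counts.sum())

    @property
    def true_taxa(self) -> frozenset[str]:
        present = (self.small_totals + self.large_counts) > 0
        return frozenset(t.taxon_id for t, p in zip(self.taxa, present) if p)

    @property
    def true_richness(self) -> int:
        return len(self.true_taxa)


def draw_community(config: CommunityConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Draw per-taxon ground-truth abundances for one sample.

    The sample total is drawn from ``config.total_abundance`` and allocated
    to taxa by a single multinomial draw with the community weights.
    """
    n = config.draw_total(rng)
    return rng.multinomial(n, config.weights)


def split_large(abundances: np.ndarray,
                large_fraction: np.ndarray | Sequence[float],
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Binomially thin each taxon into sieve-retained and tray portions.

    Every individual is independently "large" with its taxon's
    ``large_fraction``; the two portions sum to the input exactly.
    """
    abundances = np.asarray(abundances)
    if (abundances < 0).any():
        raise ValueError("abundances must be non-negative")
    large = rng.binomial(abundances, np.asarray(large_fraction, dtype=float))
    return large, abundances - large


def allocate_to_tray(small_abundances: np.ndarray,
                     geometry: TrayGeometry,
                     clustering_theta: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Place each taxon's tray individuals into cells and the edge region.

    Regions are the complete cells (area weight 1 each) plus one pooled edge
    region (weight ``geometry.edge_equivalents``). With
    ``clustering_theta = inf`` each individual lands in a region with
    probability proportional to its area (multinomial). With finite theta,
    per-taxon region probabilities are first drawn from a Dirichlet with
    concentration ``theta`` spread over the area weights
    (Dirichlet-multinomial, independent across taxa), producing spatially
    clumped, overdispersed counts with the same expectation.
    """
    if not clustering_theta > 0:
        raise ValueError("clustering_theta must be positive")
    small = np.asarray(small_abundances)
    C = geometry.n_complete_cells
    w = np.ones(C + 1)
    w[-1] = geometry.edge_equivalents
    base = w / w.sum()
    if math.isinf(clustering_theta):
        return rng.multinomial(small, base)  # broadcasts over taxa
    out = np.zeros((len(small), C + 1), dtype=np.int64)
    alpha = clustering_theta * base
    live = alpha > 0  # a zero-area edge region is excluded, not drawn
    for t, n in enumerate(small):
        if n == 0:
            continue
        p = rng.dirichlet(alpha[live])
        out[t, live] = rng.multinomial(int(n), p)
    return out


def draw_sample(config: CommunityConfig,
                geometry: TrayGeometry | None = None,
                rng: np.random.Generator | None = None) -> SampleRealization:
    """Draw one complete ground-truth sample: abundances, sieve split, tray.

    With ``rng=None`` a generator is built from ``config.rng_seed``, so an
    identical config (including seed) reproduces the realization bit for bit.
    """
    if geometry is None:
        geometry = TrayGeometry()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    abundances = draw_community(config, rng)
    large_fraction = np.array([t.large_fraction for t in config.taxa])
    large, small = split_large(abundances, large_fraction, rng)
    cells = allocate_to_tray(small, geometry, config.clustering_theta, rng)
    return SampleRealization(taxa=config.taxa, geometry=geometry,
                             cell_counts=cells.T.copy(), large_counts=large)


# --------------------------------------------------------------------------
# Calibrated presets
# --------------------------------------------------------------------------

def lognormal_weights(n_taxa: int, sigma: float) -> np.ndarray:
    """Deterministic lognormal rank-abundance weights (normalised).

    Uses the lognormal quantiles at ranks (i-0.5)/n rather than random
    draws, so a preset community is identical in every run.
    """
    nd = NormalDist()
    z = np.array([nd.inv_cdf((i - 0.5) / n_taxa) for i in range(1, n_taxa + 1)])
    w = np.exp(sigma * z[::-1])  # descending: rank 1 most abundant
    return w / w.sum()


# Taxon pools, ordered roughly from most to least abundant. Names follow the
# order/family resolution used for trap samples in practice.
_PAN_TAXA = [
    "Diptera", "Collembola", "Aphidae", "Cicadellidae", "Thysanoptera",
    "Chironomidae", "Formicidae", "Acari", "Araneae", "Coleoptera-other",
    "Hymenoptera-other", "Cercopidae", "Staphylinidae", "Carabidae",
    "Hemiptera-other", "Lepidoptera-adult", "Trichoptera-adult",
    "Curculionidae", "Chrysomelidae", "Orthoptera", "Spiderlings",
    "Psocoptera", "Neuroptera", "Ephemeroptera", "Lepidoptera-larvae",
    "Odonata", "Plecoptera", "Trichoptera-larvae", "Dermaptera", "Isopoda",
]
_PITFALL_TAXA = _PAN_TAXA + [
    "Gryllidae", "Acrididae", "Tenebrionidae", "Machillidae", "Biphylidae",
    "Auchenorrhyncha-other", "Scarabaeidae", "Elateridae", "Opiliones",
    "Chilopoda", "Diplopoda", "Silphidae", "Histeridae",
]

# Small, pale taxa that are hard to see on a white tray: reduced in-cell
# detection and a low per-individual scan probability.
_PALE = {"Aphidae", "Cercopidae", "Spiderlings", "Collembola", "Thysanoptera"}
# Large-bodied taxa: sieve-retained fractions.
_LARGE_FRACTION = {
    "Carabidae": 0.8, "Orthoptera": 0.9, "Acrididae": 0.9, "Gryllidae": 0.8,
    "Odonata": 0.9, "Tenebrionidae": 0.7, "Silphidae": 0.8,
    "Lepidoptera-adult": 0.6, "Lepidoptera-larvae": 0.4, "Dermaptera": 0.5,
    "Scarabaeidae": 0.6, "Opiliones": 0.5, "Diplopoda": 0.4, "Isopoda": 0.3,
}

_P_DETECT_CELL_PALE = 0.7
_Q_SCAN_DEFAULT = 0.5
_Q_SCAN_PALE = 0.05

# Per-preset lognormal shape, calibrated so the expected richness at the
# category's mean total matches the mean richness of that category, and the
# total-abundance range spans the category's envelope.
_PRESETS: dict[str, dict] = {
    "pan_low":          dict(taxa=_PAN_TAXA, sigma=2.577, total=(122, 237)),
    "pan_moderate":     dict(taxa=_PAN_TAXA, sigma=2.679, total=(286, 375)),
    "pan_high":         dict(taxa=_PAN_TAXA, sigma=3.190, total=(676, 5337)),
    "pitfall_low":      dict(taxa=_PITFALL_TAXA, sigma=2.540, total=(93, 164)),
    "pitfall_moderate": dict(taxa=_PITFALL_TAXA, sigma=2.804, total=(314, 384)),
    "pitfall_high":     dict(taxa=_PITFALL_TAXA, sigma=2.657, total=(504, 813)),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str,
           clustering_theta: float = math.inf,
           rng_seed: int | None = None,
           perfect_detection: bool = False) -> CommunityConfig:
    """Build one of the six calibrated trap/abundance presets.

    Names: ``pan_low``, ``pan_moderate``, ``pan_high``, ``pitfall_low``,
    ``pitfall_moderate``, ``pitfall_high``. ``perfect_detection`` overrides
    every detection probability to 1 (for bias studies of the estimator
    itself, isolating sampling error from observation error).
    """
    try:
        spec = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None
    names = spec["taxa"]
    w = lognormal_weights(len(names), spec["sigma"])
    taxa = []
    for taxon, weight in zip(names, w):
        pale = taxon in _PALE
        taxa.append(TaxonSpec(
            taxon_id=taxon,
            relative_abundance=float(weight),
            large_fraction=_LARGE_FRACTION.get(taxon, 0.0),
            p_detect_cell=1.0 if (perfect_detection or not pale)
                          else _P_DETECT_CELL_PALE,
            p_detect_scan_per_individual=1.0 if perfect_detection
                          else (_Q_SCAN_PALE if pale else _Q_SCAN_DEFAULT),
        ))
    lo, hi = spec["total"]
    return CommunityConfig(taxa=tuple(taxa),
                           total_abundance=("loguniform", lo, hi),
                           clustering_theta=clustering_theta,
                           rng_seed=rng_seed,
                           name=name)
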