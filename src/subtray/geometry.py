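"""Subsampling-plate geometry.

The laboratory apparatus is a circular turntable plate fitted with a square
metal grid. Only *complete* grid cells are selectable for subsampling; the
ring of partial cells along the plate wall is pooled into a single "edge"
region. The plate's total area, expressed in units of one cell's area, is the
extrapolation multiplier of the abundance estimator (``equivalent_cells``).

``equivalent_cells`` is stored as a configurable constant rather than being
recomputed from the plate diameter: the published multiplier (63.6) differs
slightly from the raw quotient of plate area over cell area (412/6.45 ≈ 63.9)
because of rounding in the reported areas, and the published value is the one
the estimator uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["TrayGeometry", "cell_area", "plate_area", "area_fraction"]


def cell_area(cell_side: float) -> float:
    """Area in cm² of a square grid cell with side ``cell_side`` cm."""
    if cell_side <= 0:
        raise ValueError(f"cell_side must be positive, got {cell_side}")
    return cell_side * cell_side


def plate_area(inner_diameter: float) -> float:
    """Area in cm² of the circular plate interior of diameter ``inner_diameter`` cm."""
    if inner_diameter <= 0:
        raise ValueError(f"inner_diameter must be positive, got {inner_diameter}")
    return math.pi * (inner_diameter / 2.0) ** 2


@dataclass(frozen=True)
class TrayGeometry:
    """Dimensions of the gridded subsampling plate.

    Parameters
    ----------
    inner_diameter : float
        Inner diameter of the plate in cm.
    cell_side : float
        Side length of one square grid cell in cm.
    n_complete_cells : int
        Number of complete (selectable) cells inside the plate.
    equivalent_cells : float
        Total plate area in units of one cell's area; the estimator's
        extrapolation multiplier.

    The defaults describe the published apparatus (22.9 cm plate, 2.54 cm
    cells, 45 complete cells, 63.6 cell-equivalents). All fields may be
    overridden, e.g. for a larger tray.
    """

    inner_diameter: float = 22.9
    cell_side: float = 2.54
    n_complete_cells: int = 45
    equivalent_cells: float = 63.6

    def __post_init__(self) -> None:
        if self.cell_side <= 0:
            raise ValueError("cell_side must be positive")
        if self.inner_diameter <= 2 * self.cell_side:
            raise ValueError("inner_diameter must exceed twice the cell side")
        if self.n_complete_cells < 1:
            raise ValueError("need at least one complete cell")
        # edge region may be empty (equivalent_cells == n_complete_cells) in
        # reduced test geometries; it can never be negative.
        if self.equivalent_cells < self.n_complete_cells:
            raise ValueError(
                "equivalent_cells cannot be smaller than n_complete_cells"
            )

    @property
    def cell_area(self) -> float:
        return cell_area(self.cell_side)

    @property
    def plate_area(self) -> float:
        return plate_area(self.inner_diameter)

    @property
    def edge_equivalents(self) -> float:
        """Cell-equivalents of the pooled partial-cell edge region."""
        return self.equivalent_cells - self.n_complete_cells


def area_fraction(k: int, geometry: TrayGeometry) -> float:
    """Percent of the plate's area covered by ``k`` complete cells.

    Only complete cells are selectable, so ``k`` may not exceed
    ``geometry.n_complete_cells``.
    """
    if not 0 <= k <= geometry.n_complete_cells:
        raise ValueError(
            f"k must be in [0, {geometry.n_complete_cells}], got {k}"
        )
    return 100.0 * k / geometry.equivalent_cells
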