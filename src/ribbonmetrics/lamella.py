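"""FIB-lamella biofilm census: depth geometry and cell summaries.

A lamella milled at angle *a* to the grid surface is viewed from the top;
the depth of a cell below the original sample surface is recovered from
the in-plane distance *d* between the cell centre and the leading-edge
line (where the protective platinum meets the ice) as

    depth = tan(a) * d

All lamella-plane coordinates are nanometres; areas are square microns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotations import AnnotationError, CellAnnotation, LamellaGeometry

__all__ = ["leading_edge_distance", "cell_depth", "census", "CensusSummary"]


def leading_edge_distance(cell: CellAnnotation, geom: LamellaGeometry) -> float:
    """Perpendicular distance (nm) from a cell centroid to the leading edge.

    The leading edge is treated as an infinite line through the two
    annotated points (it is drawn perpendicular to the trench walls and
    spans the lamella).
    """
    a, b = geom.leading_edge_nm
    v = b - a
    norm = np.linalg.norm(v)
    if norm == 0:
        raise AnnotationError("degenerate leading edge")
    p = cell.centroid_nm - a
    return float(abs(v[0] * p[1] - v[1] * p[0]) / norm)


def cell_depth(d_nm: float, milling_angle_deg: float) -> float:
    """Depth (nm) below the sample surface from the in-plane distance."""
    if d_nm < 0:
        raise ValueError("distance must be >= 0")
    if not (0 < milling_angle_deg < 90):
        raise ValueError("milling angle must lie in (0, 90) deg")
    return math.tan(math.radians(milling_angle_deg)) * d_nm


@dataclass
class CensusSummary:
    """Per-lamella cell census.

    ``live_fraction`` is live / (live + dead); ``live_to_dead_ratio`` is
    live / dead (``inf`` when no dead cells); both are reported because
    published "live/dead ratios" are ambiguous between the two.  When the
    lamella holds no cells the fractions are ``None`` and
    ``undefined_fractions`` is set.
    """

    n_cells: int
    n_live: int
    n_dead: int
    density_per_um2: float
    occupancy: float
    live_fraction: Optional[float]
    live_to_dead_ratio: Optional[float]
    depths_nm: dict[str, list[float]] = field(default_factory=dict)
    undefined_fractions: bool = False


def census(cells: Sequence[CellAnnotation], geom: LamellaGeometry) -> CensusSummary:
    """Summarize cell density, occupancy, viability and depth distribution.

    Occupancy is the annotated-area fraction (sum of cell areas over the
    lamella area): a 2-D proxy for the volume fraction the section
    supports.  Depths are computed per cell through the milling-angle
    geometry and grouped by live/dead state.
    """
    n_live = sum(1 for c in cells if c.state == "live")
    n_dead = len(cells) - n_live
    density = len(cells) / geom.lamella_area_um2
    occupancy = sum(c.area_um2 for c in cells) / geom.lamella_area_um2
    depths: dict[str, list[float]] = {"live": [], "dead": []}
    for c in cells:
        d = leading_edge_distance(c, geom)
        depths[c.state].append(cell_depth(d, geom.milling_angle_deg))
    if len(cells) == 0:
        return CensusSummary(
            n_cells=0, n_live=0, n_dead=0,
            density_per_um2=0.0, occupancy=0.0,
            live_fraction=None, live_to_dead_ratio=None,
            depths_nm=depths, undefined_fractions=True,
        )
    return CensusSummary(
        n_cells=len(cells), n_live=n_live, n_dead=n_dead,
        density_per_um2=density, occupancy=occupancy,
        live_fraction=n_live / len(cells),
        live_to_dead_ratio=(n_live / n_dead) if n_dead else math.inf,
        depths_nm=depths,
    )
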