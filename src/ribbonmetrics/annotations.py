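"""Line/point annotations, lamella geometry and measurement tables.

Annotations live in physical nanometres, never voxel indices, so the same
JSON file applies to a volume regardless of binning.  3-D vectors follow
the array-axis order ``(z, y, x)`` (beam, profile, transverse); the 2-D
lamella-plane coordinates are ``(x, y)`` within the lamella top view.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "LineAnnotation",
    "CellAnnotation",
    "LamellaGeometry",
    "MeasurementRecord",
    "AnnotationSet",
    "read_annotations",
    "write_annotations",
    "read_measurements",
    "write_measurements",
]


class AnnotationError(ValueError):
    """Raised when an annotation violates its invariants."""


@dataclass
class LineAnnotation:
    """A measurement line with its profile-averaging rectangle.

    The averaging rectangle is centred on the line and perpendicular to
    it: ``averaging_width_nm`` extends along the in-plane perpendicular,
    ``averaging_depth_nm`` along the direction closest to the beam axis.
    """

    id: str
    start_nm: np.ndarray
    end_nm: np.ndarray
    averaging_width_nm: float = 20.0
    averaging_depth_nm: float = 10.0

    def __post_init__(self) -> None:
        self.start_nm = np.asarray(self.start_nm, dtype=float)
        self.end_nm = np.asarray(self.end_nm, dtype=float)
        if self.start_nm.shape != (3,) or self.end_nm.shape != (3,):
            raise AnnotationError(f"line {self.id!r}: endpoints must be 3-vectors")
        if np.allclose(self.start_nm, self.end_nm):
            raise AnnotationError(f"line {self.id!r}: degenerate (start == end)")
        if not (self.averaging_width_nm > 0 and self.averaging_depth_nm > 0):
            raise AnnotationError(
                f"line {self.id!r}: averaging width/depth must be positive"
            )

    @property
    def length_nm(self) -> float:
        return float(np.linalg.norm(self.end_nm - self.start_nm))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from start to end."""
        v = self.end_nm - self.start_nm
        return v / np.linalg.norm(v)

    def reversed(self) -> "LineAnnotation":
        return LineAnnotation(
            id=self.id,
            start_nm=self.end_nm.copy(),
            end_nm=self.start_nm.copy(),
            averaging_width_nm=self.averaging_width_nm,
            averaging_depth_nm=self.averaging_depth_nm,
        )


@dataclass
class CellAnnotation:
    """One cell in a lamella top view: centroid, viability call, area."""

    id: str
    centroid_nm: np.ndarray
    state: str
    area_um2: float = 0.0

    def __post_init__(self) -> None:
        self.centroid_nm = np.asarray(self.centroid_nm, dtype=float)
        if self.centroid_nm.shape != (2,):
            raise AnnotationError(f"cell {self.id!r}: centroid must be a 2-vector")
        if self.state not in ("live", "dead"):
            raise AnnotationError(
                f"cell {self.id!r}: state must be 'live' or 'dead', got {self.state!r}"
            )
        if self.area_um2 < 0:
            raise AnnotationError(f"cell {self.id!r}: negative area")


@dataclass
class LamellaGeometry:
    """Milling geometry of one FIB lamella.

    ``milling_angle_deg`` is the angle between the grid surface and the
    ion beam; ``leading_edge_nm`` is the line (two 2-D points) drawn
    perpendicular to the trench walls where the platinum meets the ice.
    """

    milling_angle_deg: float
    leading_edge_nm: np.ndarray
    lamella_area_um2: float

    def __post_init__(self) -> None:
        if not (0 < self.milling_angle_deg < 90):
            raise AnnotationError(
                f"milling angle must lie in (0, 90) deg, got {self.milling_angle_deg}"
            )
        self.leading_edge_nm = np.asarray(self.leading_edge_nm, dtype=float)
        if self.leading_edge_nm.shape != (2, 2):
            raise AnnotationError("leading edge must be two 2-D points")
        if np.allclose(self.leading_edge_nm[0], self.leading_edge_nm[1]):
            raise AnnotationError("degenerate leading edge (identical points)")
        if not (self.lamella_area_um2 > 0):
            raise AnnotationError("lamella area must be positive")


@dataclass
class MeasurementRecord:
    """One named morphometric quantity with its provenance."""

    tomogram_id: str
    line_id: str
    quantity: str
    value_nm: float
    method: str  # "peak_to_peak" or "fwhm"
    n_peaks_used: int

    def __post_init__(self) -> None:
        if self.method not in ("peak_to_peak", "fwhm"):
            raise AnnotationError(f"unknown method {self.method!r}")
        if not (self.value_nm > 0):
            raise AnnotationError(
                f"{self.quantity}: distance/width value must be positive, "
                f"got {self.value_nm}"
            )


@dataclass
class AnnotationSet:
    """Contents of one annotation JSON file."""

    lines: list[LineAnnotation] = field(default_factory=list)
    cells: list[CellAnnotation] = field(default_factory=list)
    lamella: Optional[LamellaGeometry] = None


def read_annotations(path: str | os.PathLike) -> AnnotationSet:
    """Read annotations from JSON, validating every record.

    Unknown keys in the file are ignored; missing sections yield empty
    lists (lines, cells) or ``None`` (lamella).
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    lines = [
        LineAnnotation(
            id=str(rec["id"]),
            start_nm=rec["start_nm"],
            end_nm=rec["end_nm"],
            averaging_width_nm=float(rec.get("averaging_width_nm", 20.0)),
            averaging_depth_nm=float(rec.get("averaging_depth_nm", 10.0)),
        )
        for rec in doc.get("lines", [])
    ]
    cells = [
        CellAnnotation(
            id=str(rec["id"]),
            centroid_nm=rec["centroid_nm"],
            state=rec["state"],
            area_um2=float(rec.get("area_um2", 0.0)),
        )
        for rec in doc.get("cells", [])
    ]
    lamella = None
    if "lamella" in doc:
        rec = doc["lamella"]
        lamella = LamellaGeometry(
            milling_angle_deg=float(rec["milling_angle_deg"]),
            leading_edge_nm=rec["leading_edge_nm"],
            lamella_area_um2=float(rec["lamella_area_um2"]),
        )
    return AnnotationSet(lines=lines, cells=cells, lamella=lamella)


def write_annotations(annset: AnnotationSet, path: str | os.PathLike) -> None:
    doc: dict = {}
    if annset.lines:
        doc["lines"] = [
            {
                "id": ln.id,
                "start_nm": ln.start_nm.tolist(),
                "end_nm": ln.end_nm.tolist(),
                "averaging_width_nm": ln.averaging_width_nm,
                "averaging_depth_nm": ln.averaging_depth_nm,
            }
            for ln in annset.lines
        ]
    if annset.cells:
        doc["cells"] = [
            {
                "id": c.id,
                "centroid_nm": c.centroid_nm.tolist(),
                "state": c.state,
                "area_um2": c.area_um2,
            }
            for c in annset.cells
        ]
    if annset.lamella is not None:
        doc["lamella"] = {
            "milling_angle_deg": annset.lamella.milling_angle_deg,
            "leading_edge_nm": annset.lamella.leading_edge_nm.tolist(),
            "lamella_area_um2": annset.lamella.lamella_area_um2,
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


_MEASUREMENT_COLUMNS = [
    "tomogram_id", "line_id", "quantity", "value_nm", "method", "n_peaks_used",
]


def write_measurements(records: Iterable[MeasurementRecord],
                       path: str | os.PathLike) -> pd.DataFrame:
    """Write measurement records to CSV; returns the DataFrame written."""
    df = pd.DataFrame(
        [
            {
                "tomogram_id": r.tomogram_id,
                "line_id": r.line_id,
                "quantity": r.quantity,
                "value_nm": r.value_nm,
                "method": r.method,
                "n_peaks_used": r.n_peaks_used,
            }
            for r in records
        ],
        columns=_MEASUREMENT_COLUMNS,
    )
    df.to_csv(path, index=False)
    return df


def read_measurements(path: str | os.PathLike) -> list[MeasurementRecord]:
    df = pd.read_csv(path)
    missing = set(_MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"measurement table missing columns {sorted(missing)}")
    return [
        MeasurementRecord(
            tomogram_id=str(row.tomogram_id),
            line_id=str(row.line_id),
            quantity=str(row.quantity),
            value_nm=float(row.value_nm),
            method=str(row.method),
            n_peaks_used=int(row.n_peaks_used),
        )
        for row in df.itertuples()
    ]
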