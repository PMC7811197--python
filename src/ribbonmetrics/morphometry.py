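"""Named morphometric quantities of the ribbon/belt system.

Assembles per-line profile measurements into the quantities reported for
the cellulose machinery: OM-to-closest-sheet distance, intersheet spacing,
sheet count and width, IM-to-cortical-belt distance, belt interlayer
spacing and width, microfibril diameter, and the tight/loose
classification of the ribbon-envelope interface.

Peak labelling is positional: profile lines are annotated cytoplasm →
exterior, so along a line crossing the envelope the expected order is
belt layers, IM, OM, then sheets.  The caller states how many belt layers
the line crosses; everything beyond the OM counts as a sheet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotations import LineAnnotation
from .profiler import (DEFAULT_MIN_PROMINENCE, DEFAULT_MIN_SEPARATION_NM,
                       Peak, Profile, detect_peaks, extract_profile, fwhm,
                       peak_to_peak)
from .volume import VoxelGrid

__all__ = [
    "MeasureParams",
    "RibbonMeasurement",
    "BeltMeasurement",
    "measure_ribbon",
    "measure_belt",
    "classify_configuration",
    "estimate_fibril_diameter",
    "masked_threshold_segment",
    "MorphometryError",
]

#: tight/loose boundary (nm); a ribbon is loose iff strictly beyond this
LOOSE_THRESHOLD_NM = 40.0


class MorphometryError(ValueError):
    pass


@dataclass
class MeasureParams:
    """Knobs shared by the measurement drivers."""

    step_nm: Optional[float] = None  # default: half a voxel
    min_prominence: float = DEFAULT_MIN_PROMINENCE
    min_separation_nm: float = DEFAULT_MIN_SEPARATION_NM
    #: belt layers crossed by each envelope-normal line, cytoplasm side
    n_belt_layers: int = 0
    #: when set, keep only this many most-prominent peaks before labelling;
    #: use when the line layout is known (e.g. phantom recovery) to stop a
    #: borderline noise bump from shifting the positional labels
    n_expected_peaks: Optional[int] = None
    loose_threshold_nm: float = LOOSE_THRESHOLD_NM


@dataclass
class RibbonMeasurement:
    """Per-tomogram ribbon summary (all distances in nm)."""

    om_to_closest_sheet_nm: float
    intersheet_nm: list[float]
    n_sheets: int
    configuration: Optional[str]  # "tight" / "loose" / None when no sheets
    sheet_width_nm: Optional[float] = None
    undefined_configuration: bool = False


@dataclass
class BeltMeasurement:
    """Per-tomogram cortical-belt summary (all distances in nm)."""

    im_to_belt_nm: float
    belt_interlayer_nm: list[float]
    n_layers: int
    belt_width_nm: Optional[float] = None


@dataclass
class _LabelledPeaks:
    belt: list[Peak]
    im: Peak
    om: Peak
    sheets: list[Peak]


def _label_peaks(profile: Profile, line: LineAnnotation,
                 params: MeasureParams) -> _LabelledPeaks:
    """Assign belt/IM/OM/sheet labels to detected peaks by position order."""
    peaks = detect_peaks(profile, params.min_prominence, params.min_separation_nm)
    if (params.n_expected_peaks is not None
            and len(peaks) > params.n_expected_peaks):
        peaks = sorted(peaks, key=lambda p: p.prominence,
                       reverse=True)[: params.n_expected_peaks]
        peaks.sort(key=lambda p: p.position_nm)
    needed = params.n_belt_layers + 2
    if len(peaks) < needed:
        raise MorphometryError(
            f"line {line.id!r}: found {len(peaks)} peaks, need at least "
            f"{needed} ({params.n_belt_layers} belt + IM + OM); "
            "no OM peak resolvable"
        )
    nb = params.n_belt_layers
    return _LabelledPeaks(
        belt=peaks[:nb],
        im=peaks[nb],
        om=peaks[nb + 1],
        sheets=peaks[nb + 2:],
    )


def classify_configuration(om_to_closest_sheet_nm: float,
                           threshold_nm: float = LOOSE_THRESHOLD_NM) -> str:
    """Tight/loose call for the ribbon-envelope interface.

    Loose iff the OM-to-closest-sheet distance strictly exceeds the
    threshold (default 40 nm); at exactly the threshold the ribbon is
    still called tight.
    """
    if not (om_to_closest_sheet_nm > 0):
        raise MorphometryError("distance must be positive")
    return "loose" if om_to_closest_sheet_nm > threshold_nm else "tight"


def measure_ribbon(grid: VoxelGrid, lines: Sequence[LineAnnotation],
                   params: Optional[MeasureParams] = None,
                   width_lines: Sequence[LineAnnotation] = ()) -> RibbonMeasurement:
    """Measure the ribbon from envelope-normal profile lines.

    ``lines`` cross the envelope cytoplasm → exterior; per-line
    OM-to-closest-sheet and intersheet spacings are averaged.  ``n_sheets``
    is the number of sheet-labelled peaks (majority vote across lines).
    ``width_lines`` run transversely across a sheet and contribute an
    FWHM width estimate.
    """
    if params is None:
        params = MeasureParams()
    if not lines:
        raise MorphometryError("measure_ribbon needs at least one profile line")

    om_dists: list[float] = []
    intersheet_runs: list[list[float]] = []
    sheet_counts: list[int] = []
    for line in lines:
        profile = extract_profile(grid, line, params.step_nm)
        lab = _label_peaks(profile, line, params)
        sheet_counts.append(len(lab.sheets))
        if lab.sheets:
            om_dists.append(lab.sheets[0].position_nm - lab.om.position_nm)
            gaps = [lab.sheets[k + 1].position_nm - lab.sheets[k].position_nm
                    for k in range(len(lab.sheets) - 1)]
            intersheet_runs.append(gaps)

    n_sheets = int(np.round(np.mean(sheet_counts)))
    if not om_dists:
        return RibbonMeasurement(
            om_to_closest_sheet_nm=float("nan"),
            intersheet_nm=[],
            n_sheets=0,
            configuration=None,
            undefined_configuration=True,
            sheet_width_nm=_mean_width(grid, width_lines, params),
        )
    om_mean = float(np.mean(om_dists))
    max_gaps = max((len(r) for r in intersheet_runs), default=0)
    intersheet = [
        float(np.mean([r[k] for r in intersheet_runs if len(r) > k]))
        for k in range(max_gaps)
    ]
    return RibbonMeasurement(
        om_to_closest_sheet_nm=om_mean,
        intersheet_nm=intersheet,
        n_sheets=n_sheets,
        configuration=classify_configuration(om_mean, params.loose_threshold_nm),
        sheet_width_nm=_mean_width(grid, width_lines, params),
    )


def _mean_width(grid: VoxelGrid, width_lines: Sequence[LineAnnotation],
                params: MeasureParams) -> Optional[float]:
    if not width_lines:
        return None
    widths = []
    for line in width_lines:
        profile = extract_profile(grid, line, params.step_nm)
        peaks = detect_peaks(profile, params.min_prominence,
                             params.min_separation_nm)
        if not peaks:
            raise MorphometryError(f"width line {line.id!r}: no peak found")
        main = max(peaks, key=lambda p: p.prominence)
        widths.append(fwhm(profile, main))
    return float(np.mean(widths))


def measure_belt(grid: VoxelGrid, lines: Sequence[LineAnnotation],
                 params: Optional[MeasureParams] = None,
                 width_lines: Sequence[LineAnnotation] = ()) -> BeltMeasurement:
    """Measure the cortical belt from envelope-normal profile lines.

    Requires ``params.n_belt_layers >= 1``; the IM-to-belt distance is
    taken from the IM peak to the nearest belt-layer peak.
    """
    if params is None:
        params = MeasureParams(n_belt_layers=1)
    if params.n_belt_layers < 1:
        raise MorphometryError(
            "measure_belt requires n_belt_layers >= 1 (no belt_layer label)"
        )
    if not lines:
        raise MorphometryError("measure_belt needs at least one profile line")

    im_dists: list[float] = []
    interlayer_runs: list[list[float]] = []
    layer_counts: list[int] = []
    for line in lines:
        profile = extract_profile(grid, line, params.step_nm)
        lab = _label_peaks(profile, line, params)
        layer_counts.append(len(lab.belt))
        im_dists.append(lab.im.position_nm - lab.belt[-1].position_nm)
        gaps = [lab.belt[k + 1].position_nm - lab.belt[k].position_nm
                for k in range(len(lab.belt) - 1)]
        interlayer_runs.append(gaps)

    max_gaps = max((len(r) for r in interlayer_runs), default=0)
    interlayer = [
        float(np.mean([r[k] for r in interlayer_runs if len(r) > k]))
        for k in range(max_gaps)
    ]
    return BeltMeasurement(
        im_to_belt_nm=float(np.mean(im_dists)),
        belt_interlayer_nm=interlayer,
        n_layers=int(np.round(np.mean(layer_counts))),
        belt_width_nm=_mean_width(grid, width_lines, params),
    )


def estimate_fibril_diameter(grid: VoxelGrid, line: LineAnnotation,
                             axis_direction: Optional[np.ndarray] = None,
                             params: Optional[MeasureParams] = None) -> float:
    """FWHM diameter of a microfibril crossed perpendicular to its axis.

    Under defocus blur this is an upper bound on the true diameter: blur
    only ever widens the FWHM of a convex density peak, which is why
    reported fibril diameters are upper limits.

    ``axis_direction``, when given, is used to verify the line is roughly
    perpendicular to the fibril (within 30 degrees); a line running along
    the fibril is rejected.
    """
    if params is None:
        params = MeasureParams()
    if axis_direction is not None:
        u = line.direction
        a = np.asarray(axis_direction, dtype=float)
        a = a / np.linalg.norm(a)
        if abs(float(np.dot(u, a))) > 0.5:
            raise MorphometryError(
                f"line {line.id!r} runs within 60 deg of the fibril axis; "
                "a perpendicular crossing is required"
            )
    profile = extract_profile(grid, line, params.step_nm)
    peaks = detect_peaks(profile, params.min_prominence, params.min_separation_nm)
    if not peaks:
        raise MorphometryError(f"line {line.id!r}: no fibril peak found")
    main = max(peaks, key=lambda p: p.prominence)
    return fwhm(profile, main)


def masked_threshold_segment(grid: VoxelGrid, mask: np.ndarray,
                             threshold: float) -> tuple[np.ndarray, float]:
    """Threshold segmentation restricted to a hand-drawn mask.

    Mirrors the masked isosurface workflow: voxels are selected iff they
    lie inside the mask AND their density is >= threshold; the returned
    fraction is selected voxels / mask voxels.  The mask confines the
    isosurface so the threshold can be raised without picking up
    background noise elsewhere.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise MorphometryError(
            f"mask shape {mask.shape} does not match grid shape {grid.shape}"
        )
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise MorphometryError("empty mask")
    selected = mask & (grid.data >= threshold)
    return selected, float(selected.sum()) / n_mask
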