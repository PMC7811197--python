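"""Synthetic cryo-ET phantoms of the cellulose-producing cell envelope.

The generator renders the layered geometry seen on the cellulose-secreting
side of *Gluconacetobacter* cells — outer and inner membrane, one or more
extracellular cellulose sheets, and the stacked cytoplasmic cortical belt
— as soft-edged density slabs, plus cylindrical microfibrils, and then
degrades the volume with the three dominant cryo-ET artifacts:

* defocus contrast loss, modelled as an isotropic Gaussian PSF;
* the missing wedge of a limited tilt range (hard Fourier mask), which
  elongates features along the beam axis;
* additive white Gaussian detector/reconstruction noise.

Every phantom carries a ground-truth sidecar listing the true peak-to-peak
spacings and widths, so the downstream profile metrology can be validated
by parameter recovery.  Density polarity is "bright = dense": features are
positive peaks on a zero background, matching the convention of normalized
density-profile plots; inverting real cryo-ET contrast is the caller's
responsibility at import time.

Axis convention (shared with :mod:`ribbonmetrics.volume`): array axis 0 is
the beam (Z), axis 1 the profile axis (normal to the envelope, cytoplasm at
low coordinate, exterior at high coordinate), axis 2 the transverse
in-plane axis.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.fft
from scipy import ndimage

from .volume import VoxelGrid

__all__ = [
    "LayerSpec",
    "CylinderSpec",
    "PhantomSpec",
    "ImagingModel",
    "GroundTruth",
    "render_phantom",
    "apply_psf",
    "apply_missing_wedge",
    "add_noise",
    "apply_imaging",
    "canonical_ribbon_phantom",
    "write_ground_truth",
    "read_ground_truth",
]

LAYER_LABELS = ("OM", "IM", "sheet", "belt_layer")

#: edge softness of rendered features, in voxels (kept below one voxel so
#: that peak positions are defined to sub-voxel accuracy by construction)
EDGE_SOFTNESS_VOXELS = 0.5

# ---------------------------------------------------------------------------
# canonical geometry (see docs/methods.md for the rationale of each choice)
# ---------------------------------------------------------------------------
CANONICAL_VOXEL_NM = 0.7
CANONICAL_SHAPE = (128, 256, 256)
#: peak-to-peak spacings (nm) the canonical phantoms are built to; these are
#: the mean values measured on G. hansenii tomograms
TIGHT_OM_TO_SHEET_NM = 16.0
TIGHT_INTERSHEET_NM = 16.0
TIGHT_IM_TO_BELT_NM = 24.0
TIGHT_BELT_INTERLAYER_NM = 15.0
LOOSE_OM_TO_SHEET_NM = 99.0
SHEET_WIDTH_NM = 38.0
BELT_WIDTH_NM = 47.0
FIBRIL_DIAMETER_NM = 11.0
#: IM-OM separation is not a measured quantity here; 30 nm is a typical
#: Gram-negative periplasmic span and is recorded in the ground truth
IM_OM_SEPARATION_NM = 30.0
MEMBRANE_THICKNESS_NM = 6.0
SHEET_THICKNESS_NM = 8.0  # constrained only to be thinner than the intersheet spacing
BELT_THICKNESS_NM = 6.0
MEMBRANE_AMPLITUDE = 1.0
SHEET_AMPLITUDE = 0.8
BELT_AMPLITUDE = 0.7
#: canonical signal-to-noise: strongest feature amplitude / noise sigma
CANONICAL_SNR = 2.0
CANONICAL_PSF_SIGMA_NM = 2.0
CANONICAL_TILT_RANGE_DEG = 60.0


class PhantomError(ValueError):
    """Raised for invalid phantom specifications."""


@dataclass
class LayerSpec:
    """A slab perpendicular to the profile axis.

    ``center_offset_nm`` is signed, measured along the profile axis from
    the phantom's reference position (positive = toward the cell exterior).
    ``width_nm`` limits the slab's extent along the transverse axis;
    ``inf`` means it spans the whole grid.
    """

    label: str
    center_offset_nm: float
    thickness_nm: float
    amplitude: float
    width_nm: float = math.inf

    def __post_init__(self) -> None:
        if self.label not in LAYER_LABELS:
            raise PhantomError(
                f"unknown layer label {self.label!r}; expected one of {LAYER_LABELS}"
            )
        if not (self.thickness_nm > 0):
            raise PhantomError(f"layer {self.label}: thickness must be positive")
        if not (self.amplitude > 0):
            raise PhantomError(f"layer {self.label}: amplitude must be positive")
        if not (self.width_nm > 0):
            raise PhantomError(f"layer {self.label}: width must be positive")


@dataclass
class CylinderSpec:
    """A soft-edged cylinder (microfibril)."""

    diameter_nm: float
    axis_direction: np.ndarray
    center_nm: np.ndarray
    length_nm: float
    amplitude: float

    def __post_init__(self) -> None:
        if not (self.diameter_nm > 0):
            raise PhantomError("cylinder diameter must be positive")
        if not (self.length_nm > 0):
            raise PhantomError("cylinder length must be positive")
        if not (self.amplitude > 0):
            raise PhantomError("cylinder amplitude must be positive")
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        n = np.linalg.norm(self.axis_direction)
        if n == 0:
            raise PhantomError("cylinder axis direction must be non-zero")
        self.axis_direction = self.axis_direction / n
        self.center_nm = np.asarray(self.center_nm, dtype=float)


@dataclass
class PhantomSpec:
    """Parametric description of a layered phantom."""

    grid_shape: tuple[int, int, int] = CANONICAL_SHAPE
    voxel_size_nm: float = CANONICAL_VOXEL_NM
    layers: list[LayerSpec] = field(default_factory=list)
    cylinders: list[CylinderSpec] = field(default_factory=list)
    background: float = 0.0
    #: absolute position (nm, along axis 1) that layer offsets are measured from
    reference_position_nm: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.voxel_size_nm > 0):
            raise PhantomError("voxel size must be positive")
        if len(self.grid_shape) != 3 or any(n < 2 for n in self.grid_shape):
            raise PhantomError(f"grid shape must be a 3-D shape, got {self.grid_shape}")

    @property
    def reference_nm(self) -> float:
        if self.reference_position_nm is not None:
            return self.reference_position_nm
        return 0.5 * self.grid_shape[1] * self.voxel_size_nm

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size_nm": self.voxel_size_nm,
            "background": self.background,
            "reference_position_nm": self.reference_nm,
            "layers": [
                {
                    "label": l.label,
                    "center_offset_nm": l.center_offset_nm,
                    "thickness_nm": l.thickness_nm,
                    "amplitude": l.amplitude,
                    "width_nm": None if math.isinf(l.width_nm) else l.width_nm,
                }
                for l in self.layers
            ],
            "cylinders": [
                {
                    "diameter_nm": c.diameter_nm,
                    "axis_direction": c.axis_direction.tolist(),
                    "center_nm": c.center_nm.tolist(),
                    "length_nm": c.length_nm,
                    "amplitude": c.amplitude,
                }
                for c in self.cylinders
            ],
        }


@dataclass
class ImagingModel:
    """Cryo-ET degradation parameters.

    ``psf_sigma_nm = 0``, ``tilt_range_deg = 90`` and ``noise_sigma = 0``
    together form the identity model.  ``tilt_range_deg`` is the half
    range: 60 means a ±60 deg tilt series.
    """

    psf_sigma_nm: float = 0.0
    tilt_range_deg: float = 90.0
    tilt_axis: str = "x"
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_nm < 0:
            raise PhantomError("psf_sigma_nm must be >= 0")
        if not (0 < self.tilt_range_deg <= 90):
            raise PhantomError("tilt_range_deg must lie in (0, 90]")
        if self.tilt_axis not in ("x", "y"):
            raise PhantomError("tilt_axis must be 'x' or 'y'")
        if self.noise_sigma < 0:
            raise PhantomError("noise_sigma must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (self.psf_sigma_nm == 0 and self.tilt_range_deg == 90
                and self.noise_sigma == 0)

    def to_dict(self) -> dict:
        return {
            "psf_sigma_nm": self.psf_sigma_nm,
            "tilt_range_deg": self.tilt_range_deg,
            "tilt_axis": self.tilt_axis,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
        }


@dataclass
class GroundTruth:
    """True values (nm) of the named morphometric quantities."""

    quantities: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.quantities[name]

    def __contains__(self, name: str) -> bool:
        return name in self.quantities


# axis-name mapping: the two in-plane axes of the (beam, profile, transverse)
# grid; "y" is the profile axis (1), "x" the transverse axis (2)
_INPLANE_AXIS = {"y": 1, "x": 2}


def _soft_slab_profile(coords_nm: np.ndarray, center_nm: float,
                       thickness_nm: float, softness_nm: float) -> np.ndarray:
    """Top-hat of given width with error-function edges (area-preserving)."""
    from scipy.special import erf
    s = max(softness_nm, 1e-6)
    lo = (coords_nm - (center_nm - thickness_nm / 2)) / (math.sqrt(2) * s)
    hi = (coords_nm - (center_nm + thickness_nm / 2)) / (math.sqrt(2) * s)
    return 0.5 * (erf(lo) - erf(hi))


def render_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, GroundTruth]:
    """Render a phantom spec into a density volume plus its ground truth.

    Layers are separable products of a soft top-hat along the profile axis
    and (if finite width) a soft top-hat along the transverse axis;
    cylinders are soft discs swept along their axis.  The ground truth
    records every peak-to-peak spacing implied by the layer offsets.
    """
    nz, ny, nx = spec.grid_shape
    vox = spec.voxel_size_nm
    soft = EDGE_SOFTNESS_VOXELS * vox
    ref = spec.reference_nm
    y_nm = (np.arange(ny) + 0.0) * vox  # voxel centres, origin 0
    x_nm = (np.arange(nx) + 0.0) * vox
    z_nm = (np.arange(nz) + 0.0) * vox

    data = np.full(spec.grid_shape, spec.background, dtype=np.float32)

    for layer in spec.layers:
        c = ref + layer.center_offset_nm
        if c - layer.thickness_nm / 2 - 3 * soft < 0 or \
           c + layer.thickness_nm / 2 + 3 * soft > ny * vox:
            raise PhantomError(
                f"layer {layer.label!r} at offset {layer.center_offset_nm} nm "
                f"(absolute {c:.1f} nm) does not fit inside the grid "
                f"(profile extent {ny * vox:.1f} nm)"
            )
        prof = _soft_slab_profile(y_nm, c, layer.thickness_nm, soft)
        if math.isinf(layer.width_nm):
            data += (layer.amplitude * prof)[None, :, None].astype(np.float32)
        else:
            xc = 0.5 * nx * vox
            if layer.width_nm > nx * vox:
                raise PhantomError(
                    f"layer {layer.label!r}: width {layer.width_nm} nm exceeds "
                    f"the transverse grid extent {nx * vox:.1f} nm"
                )
            trans = _soft_slab_profile(x_nm, xc, layer.width_nm, soft)
            data += layer.amplitude * prof[None, :, None] * trans[None, None, :]

    for cyl in spec.cylinders:
        u = cyl.axis_direction
        zc = (z_nm - cyl.center_nm[0]).reshape(-1, 1, 1)
        yc = (y_nm - cyl.center_nm[1]).reshape(1, -1, 1)
        xc = (x_nm - cyl.center_nm[2]).reshape(1, 1, -1)
        t = u[0] * zc + u[1] * yc + u[2] * xc
        r2 = zc ** 2 + yc ** 2 + xc ** 2 - t ** 2
        r = np.sqrt(np.maximum(r2, 0.0))
        radial = np.clip((cyl.diameter_nm / 2 - r) / soft + 0.5, 0.0, 1.0)
        axial = np.clip((cyl.length_nm / 2 - np.abs(t)) / soft + 0.5, 0.0, 1.0)
        body = cyl.amplitude * radial * axial
        if body[0].max() > 1e-3 * cyl.amplitude or body[-1].max() > 1e-3 * cyl.amplitude:
            raise PhantomError("cylinder extends outside the grid along the beam axis")
        data += body.astype(np.float32)

    return VoxelGrid(data=data, voxel_size_nm=vox), _ground_truth_from_spec(spec)


def _ground_truth_from_spec(spec: PhantomSpec) -> GroundTruth:
    by_label: dict[str, list[LayerSpec]] = {}
    for layer in spec.layers:
        by_label.setdefault(layer.label, []).append(layer)
    for layers in by_label.values():
        layers.sort(key=lambda l: l.center_offset_nm)

    q: dict[str, float] = {}
    oms = by_label.get("OM", [])
    ims = by_label.get("IM", [])
    sheets = by_label.get("sheet", [])
    belts = by_label.get("belt_layer", [])

    q["n_sheets"] = float(len(sheets))
    if oms and sheets:
        q["om_to_sheet"] = min(s.center_offset_nm for s in sheets) - oms[0].center_offset_nm
    if len(sheets) >= 2:
        gaps = np.diff([s.center_offset_nm for s in sheets])
        q["intersheet"] = float(np.mean(gaps))
    if oms and ims:
        q["im_om_separation"] = oms[0].center_offset_nm - ims[0].center_offset_nm
    if ims and belts:
        q["im_to_belt"] = ims[0].center_offset_nm - belts[-1].center_offset_nm
    if len(belts) >= 2:
        gaps = np.diff([b.center_offset_nm for b in belts])
        q["belt_interlayer"] = float(np.mean(gaps))
    finite_sheets = [s for s in sheets if not math.isinf(s.width_nm)]
    if finite_sheets:
        q["sheet_width"] = finite_sheets[0].width_nm
    finite_belts = [b for b in belts if not math.isinf(b.width_nm)]
    if finite_belts:
        q["belt_width"] = finite_belts[0].width_nm
    if spec.cylinders:
        q["fibril_diameter"] = spec.cylinders[0].diameter_nm
    return GroundTruth(quantities=q)


# ---------------------------------------------------------------------------
# imaging model
# ---------------------------------------------------------------------------

def apply_psf(grid: VoxelGrid, psf_sigma_nm: float) -> VoxelGrid:
    """Isotropic Gaussian blur with a physical sigma (defocus proxy).

    Uses wrap-around boundaries so that the summed density is conserved
    exactly; features are rendered well inside the grid, so wrap-around
    leakage is negligible for them.
    """
    if psf_sigma_nm < 0:
        raise PhantomError("psf_sigma_nm must be >= 0")
    if psf_sigma_nm == 0:
        return VoxelGrid(grid.data.copy(), grid.voxel_size_nm, grid.origin_nm.copy())
    sigma_vox = psf_sigma_nm / grid.voxel_size_nm
    out = ndimage.gaussian_filter(grid.data.astype(np.float32, copy=False),
                                  sigma=sigma_vox, mode="wrap")
    return VoxelGrid(out, grid.voxel_size_nm, grid.origin_nm.copy())


def _wedge_keep_mask(shape, tilt_range_deg: float, tilt_axis: str) -> np.ndarray:
    """Boolean mask (True = keep), broadcastable over the rfftn grid.

    The last axis carries the half-spectrum (rfft) frequencies.
    """
    perp = 1 if _INPLANE_AXIS[tilt_axis] == 2 else 2
    kz = np.abs(np.fft.fftfreq(shape[0])).reshape(-1, 1, 1)
    if perp == 1:
        kp = np.abs(np.fft.fftfreq(shape[1])).reshape(1, -1, 1)
    else:
        kp = np.abs(np.fft.rfftfreq(shape[2])).reshape(1, 1, -1)
    cot = 1.0 / math.tan(math.radians(tilt_range_deg))
    # inside the missing wedge: direction closer than (90 - tilt_range) deg
    # to the beam axis, i.e. |k_perp| < |k_beam| * cot(tilt_range)
    missing = kp < kz * cot
    return ~missing


def apply_missing_wedge(grid: VoxelGrid, tilt_range_deg: float,
                        tilt_axis: str = "x") -> VoxelGrid:
    """Zero the Fourier wedge left unsampled by a limited tilt range.

    The beam axis is grid axis 0.  Tilting about ``tilt_axis`` samples
    Fourier space in the plane perpendicular to it up to ±``tilt_range``;
    coefficients whose (beam, in-plane) direction lies within
    ``90 - tilt_range`` degrees of the beam axis are removed.  Frequencies
    along the tilt axis itself are untouched, which is why in-plane
    distances measured along it stay unbiased while beam-axis extents
    elongate.
    """
    if not (0 < tilt_range_deg <= 90):
        raise PhantomError("tilt_range_deg must lie in (0, 90]")
    if tilt_axis not in _INPLANE_AXIS:
        raise PhantomError("tilt_axis must be 'x' or 'y'")
    if tilt_range_deg == 90:
        return VoxelGrid(grid.data.copy(), grid.voxel_size_nm, grid.origin_nm.copy())
    data = grid.data.astype(np.float32, copy=False)
    F = scipy.fft.rfftn(data)
    keep = _wedge_keep_mask(data.shape, tilt_range_deg, tilt_axis)
    F *= keep
    out = scipy.fft.irfftn(F, s=data.shape).astype(np.float32)
    return VoxelGrid(out, grid.voxel_size_nm, grid.origin_nm.copy())


def add_noise(grid: VoxelGrid, noise_sigma: float, seed: int) -> VoxelGrid:
    """Add white zero-mean Gaussian noise; identical seed, identical output."""
    if noise_sigma < 0:
        raise PhantomError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return VoxelGrid(grid.data.copy(), grid.voxel_size_nm, grid.origin_nm.copy())
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sigma, size=grid.shape).astype(np.float32)
    return VoxelGrid(grid.data + noise, grid.voxel_size_nm, grid.origin_nm.copy())


def apply_imaging(grid: VoxelGrid, imaging: ImagingModel) -> VoxelGrid:
    """PSF blur, then the missing wedge, then additive noise."""
    out = apply_psf(grid, imaging.psf_sigma_nm)
    out = apply_missing_wedge(out, imaging.tilt_range_deg, imaging.tilt_axis)
    out = add_noise(out, imaging.noise_sigma, imaging.seed)
    return out


# ---------------------------------------------------------------------------
# canonical variants
# ---------------------------------------------------------------------------

def canonical_spec(variant: str) -> PhantomSpec:
    """The fixed study-condition phantom spec for one variant.

    ``tight``: OM with two sheets outside at the tight-configuration
    spacings and a three-layer cortical belt inside the IM.  ``loose``: a
    single sheet detached far from the OM.  ``width``: finite-width sheet
    and belt slabs for FWHM width recovery.  ``fibril``: a cylinder normal
    to the OM.
    """
    mem = MEMBRANE_THICKNESS_NM
    if variant == "tight":
        layers = [
            LayerSpec("OM", 0.0, mem, MEMBRANE_AMPLITUDE),
            LayerSpec("IM", -IM_OM_SEPARATION_NM, mem, MEMBRANE_AMPLITUDE),
            LayerSpec("sheet", TIGHT_OM_TO_SHEET_NM, SHEET_THICKNESS_NM, SHEET_AMPLITUDE),
            LayerSpec("sheet", TIGHT_OM_TO_SHEET_NM + TIGHT_INTERSHEET_NM,
                      SHEET_THICKNESS_NM, SHEET_AMPLITUDE),
            LayerSpec("belt_layer", -IM_OM_SEPARATION_NM - TIGHT_IM_TO_BELT_NM,
                      BELT_THICKNESS_NM, BELT_AMPLITUDE),
            LayerSpec("belt_layer",
                      -IM_OM_SEPARATION_NM - TIGHT_IM_TO_BELT_NM - TIGHT_BELT_INTERLAYER_NM,
                      BELT_THICKNESS_NM, BELT_AMPLITUDE),
            LayerSpec("belt_layer",
                      -IM_OM_SEPARATION_NM - TIGHT_IM_TO_BELT_NM - 2 * TIGHT_BELT_INTERLAYER_NM,
                      BELT_THICKNESS_NM, BELT_AMPLITUDE),
        ]
        # offsets span [-84, +32]; put the OM so the stack is centred
        ref = 0.5 * CANONICAL_SHAPE[1] * CANONICAL_VOXEL_NM + 26.0
        return PhantomSpec(layers=layers, reference_position_nm=ref)
    if variant == "loose":
        layers = [
            LayerSpec("OM", 0.0, mem, MEMBRANE_AMPLITUDE),
            LayerSpec("IM", -IM_OM_SEPARATION_NM, mem, MEMBRANE_AMPLITUDE),
            LayerSpec("sheet", LOOSE_OM_TO_SHEET_NM, SHEET_THICKNESS_NM, SHEET_AMPLITUDE),
        ]
        ref = 0.5 * CANONICAL_SHAPE[1] * CANONICAL_VOXEL_NM - 34.0
        return PhantomSpec(layers=layers, reference_position_nm=ref)
    if variant == "width":
        layers = [
            LayerSpec("sheet", TIGHT_OM_TO_SHEET_NM, SHEET_THICKNESS_NM,
                      SHEET_AMPLITUDE, width_nm=SHEET_WIDTH_NM),
            LayerSpec("belt_layer", -IM_OM_SEPARATION_NM - TIGHT_IM_TO_BELT_NM,
                      BELT_THICKNESS_NM, BELT_AMPLITUDE, width_nm=BELT_WIDTH_NM),
        ]
        ref = 0.5 * CANONICAL_SHAPE[1] * CANONICAL_VOXEL_NM + 19.0
        return PhantomSpec(layers=layers, reference_position_nm=ref)
    if variant == "fibril":
        vox = CANONICAL_VOXEL_NM
        center = np.array([0.5 * CANONICAL_SHAPE[0] * vox,
                           0.5 * CANONICAL_SHAPE[1] * vox,
                           0.5 * CANONICAL_SHAPE[2] * vox])
        cyl = CylinderSpec(
            diameter_nm=FIBRIL_DIAMETER_NM,
            axis_direction=np.array([0.0, 1.0, 0.0]),  # normal to the OM
            center_nm=center,
            length_nm=60.0,
            amplitude=SHEET_AMPLITUDE,
        )
        return PhantomSpec(cylinders=[cyl])
    raise PhantomError(
        f"unknown phantom variant {variant!r}; expected tight/loose/width/fibril"
    )


def canonical_ribbon_phantom(variant: str,
                             imaging: ImagingModel) -> tuple[VoxelGrid, GroundTruth]:
    """Render one canonical variant and push it through the imaging model."""
    spec = canonical_spec(variant)
    grid, truth = render_phantom(spec)
    return apply_imaging(grid, imaging), truth


def canonical_imaging(seed: int = 0) -> ImagingModel:
    """The canonical degradation: sigma 2 nm blur, ±60 deg wedge, SNR 2."""
    return ImagingModel(
        psf_sigma_nm=CANONICAL_PSF_SIGMA_NM,
        tilt_range_deg=CANONICAL_TILT_RANGE_DEG,
        tilt_axis="x",
        noise_sigma=MEMBRANE_AMPLITUDE / CANONICAL_SNR,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ground-truth sidecar I/O
# ---------------------------------------------------------------------------

def write_ground_truth(path: str | os.PathLike, truth: GroundTruth,
                       spec: PhantomSpec, imaging: ImagingModel) -> None:
    doc = {
        "quantities": truth.quantities,
        "spec": spec.to_dict(),
        "imaging": imaging.to_dict(),
        "seed": imaging.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_ground_truth(path: str | os.PathLike) -> GroundTruth:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return GroundTruth(quantities={k: float(v) for k, v in doc["quantities"].items()})
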