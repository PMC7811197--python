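"""Volume container and MRC2014 input/output.

The pipeline's fixed axis convention is ``(beam, profile, transverse)``:
array axis 0 is the electron-beam direction (Z of the microscope), axes 1
and 2 span the well-sampled in-plane directions.  All physical coordinates
are nanometres and are ordered like the array axes, ``(z, y, x)``.
A voxel's physical position is its centre: ``pos_nm = origin_nm + index *
voxel_size_nm``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = ["VoxelGrid", "read_volume", "write_volume"]

#: relative tolerance used to decide whether an MRC header is isotropic
_ISOTROPY_RTOL = 1e-3


class VolumeError(ValueError):
    """Raised for malformed or unsupported volume files."""


@dataclass
class VoxelGrid:
    """A 3-D scalar density field with a physical voxel size.

    Parameters
    ----------
    data:
        3-D array ordered ``(beam, profile, transverse)``.
    voxel_size_nm:
        Isotropic voxel edge length in nanometres.
    origin_nm:
        Physical position of voxel ``(0, 0, 0)``, ``(z, y, x)`` in nm.
    """

    data: np.ndarray
    voxel_size_nm: float
    origin_nm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(
                f"VoxelGrid requires 3-D data, got {self.data.ndim}-D"
            )
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("VoxelGrid data contains non-finite values")
        if not (self.voxel_size_nm > 0):
            raise VolumeError(
                f"voxel_size_nm must be positive, got {self.voxel_size_nm}"
            )
        self.origin_nm = np.asarray(self.origin_nm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent_nm(self) -> np.ndarray:
        """Physical size of the grid along each axis in nm."""
        return np.asarray(self.shape) * self.voxel_size_nm

    def index_to_nm(self, index) -> np.ndarray:
        """Physical position (nm) of a (possibly fractional) voxel index."""
        return self.origin_nm + np.asarray(index, dtype=float) * self.voxel_size_nm

    def nm_to_index(self, pos_nm) -> np.ndarray:
        """Fractional voxel index of a physical position (nm)."""
        return (np.asarray(pos_nm, dtype=float) - self.origin_nm) / self.voxel_size_nm

    def contains_nm(self, pos_nm, pad_voxels: float = 0.0) -> bool:
        """True if ``pos_nm`` lies inside the grid, shrunk by ``pad_voxels``."""
        idx = self.nm_to_index(pos_nm)
        hi = np.asarray(self.shape) - 1 - pad_voxels
        return bool(np.all(idx >= pad_voxels) and np.all(idx <= hi))


def read_volume(path: str | os.PathLike) -> VoxelGrid:
    """Read an MRC2014/CCP4 volume.

    The header cell is interpreted in angstroms (the cryo-EM convention)
    and converted to nanometres.  Anisotropic voxel spacings are rejected:
    every downstream distance assumes a single isotropic spacing.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise VolumeError(f"cannot read MRC volume {path!r}: header/file malformed ({exc})")
    grid = ccp4.grid
    dims = np.array([grid.nu, grid.nv, grid.nw])
    if np.any(dims <= 1):
        raise VolumeError(
            f"{path!r}: expected a 3-D volume, got grid dimensions {tuple(dims)}"
        )
    cell = grid.unit_cell
    spacings_nm = np.array([cell.a, cell.b, cell.c]) / dims / 10.0
    if np.any(spacings_nm <= 0):
        raise VolumeError(f"{path!r}: non-positive voxel size in header cell")
    if np.ptp(spacings_nm) > _ISOTROPY_RTOL * spacings_nm.mean():
        raise VolumeError(
            f"{path!r}: anisotropic voxel spacing {tuple(np.round(spacings_nm, 4))} nm; "
            "the pipeline assumes isotropic voxels"
        )
    data = np.array(grid, copy=True)
    origin_nm = np.array(
        [ccp4.header_float(50), ccp4.header_float(51), ccp4.header_float(52)]
    ) / 10.0
    return VoxelGrid(data=data, voxel_size_nm=float(spacings_nm.mean()),
                     origin_nm=origin_nm)


def write_volume(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write ``grid`` as a 32-bit float MRC2014 map (cell in angstroms)."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.data, dtype=np.float32))
    a, b, c = (np.asarray(grid.shape) * grid.voxel_size_nm * 10.0)
    ccp4.grid.unit_cell = gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    oz, oy, ox = np.asarray(grid.origin_nm, dtype=float) * 10.0
    ccp4.set_header_float(50, oz)
    ccp4.set_header_float(51, oy)
    ccp4.set_header_float(52, ox)
    ccp4.write_ccp4_map(str(path))
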