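"""Voxel grids and MRC/CCP4 map I/O.

A :class:`VoxelGrid` is the package-wide container for a 3D density map:
a float32 array indexed ``[z, y, x]`` (section axis slowest, matching the
MRC2014 convention) plus the physical metadata needed to map array indices
to Cartesian coordinates.  All other modules assume this one canonical
layout; files whose fast/medium/slow axes are permuted are transposed on
read and the original permutation is recorded.

The Cartesian position of voxel ``data[k, j, i]`` is::

    origin + (i * voxel_size[0], j * voxel_size[1], k * voxel_size[2])

with ``origin`` and ``voxel_size`` always in (x, y, z) order and Å units.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gemmi
import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "MapFormatError",
    "UnsupportedMapError",
    "read_map",
    "write_map",
    "resample_to_grid",
]


class MapFormatError(ValueError):
    """The file is not a readable MRC/CCP4 volume."""


class UnsupportedMapError(ValueError):
    """The map is valid but outside scope (e.g. non-orthogonal axes)."""


_ANGLE_TOL = 1e-3  # degrees


@dataclasses.dataclass
class VoxelGrid:
    """A 3D scalar density field with physical metadata.

    Parameters
    ----------
    data:
        float32 array indexed ``[z, y, x]``.
    voxel_size:
        Å per voxel along (x, y, z); all entries strictly positive.
    origin:
        Cartesian Å position of the grid point at index (0, 0, 0),
        in (x, y, z) order.
    axis_order:
        The on-disk (mapc, mapr, maps) permutation the file used before
        canonicalization; ``(1, 2, 3)`` for grids created in memory.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: tuple[int, int, int] = (1, 2, 3)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if any(n < 1 for n in self.data.shape):
            raise ValueError(f"degenerate grid shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.voxel_size) != 3 or len(self.origin) != 3:
            raise ValueError("voxel_size and origin must be 3-tuples")
        if not all(np.isfinite(v) and v > 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive and finite, got {self.voxel_size}")
        if not all(np.isfinite(o) for o in self.origin):
            raise ValueError(f"origin must be finite, got {self.origin}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape in ``(nz, ny, nx)`` order."""
        return self.data.shape

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        """A new grid sharing this grid's metadata but holding ``data``."""
        return VoxelGrid(data, self.voxel_size, self.origin, self.axis_order)

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.data.copy(), self.voxel_size, self.origin, self.axis_order)

    def index_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis Cartesian coordinates (x, y, z) of the grid points."""
        nz, ny, nx = self.data.shape
        vx, vy, vz = self.voxel_size
        ox, oy, oz = self.origin
        return (
            ox + vx * np.arange(nx),
            oy + vy * np.arange(ny),
            oz + vz * np.arange(nz),
        )


def read_map(path: str | Path) -> VoxelGrid:
    """Read an MRC/CCP4 volume and canonicalize it.

    The returned grid is indexed ``[z, y, x]`` regardless of the file's
    fast/medium/slow axis permutation.  The origin is taken from the MRC2014
    ORIGIN header words when any is nonzero, otherwise from
    ``nstart × voxel_size`` (CCP4 convention).

    Raises
    ------
    MapFormatError
        If the file cannot be parsed or contains non-finite voxels.
    UnsupportedMapError
        If the cell angles are not 90° (non-orthogonal axes).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"{path}: not a readable MRC/CCP4 map ({exc})") from exc

    cell = m.grid.unit_cell
    if any(abs(a - 90.0) > _ANGLE_TOL for a in (cell.alpha, cell.beta, cell.gamma)):
        raise UnsupportedMapError(
            f"{path}: non-orthogonal cell angles "
            f"({cell.alpha:.3f}, {cell.beta:.3f}, {cell.gamma:.3f}); only "
            "orthogonal-axis maps are supported"
        )

    axis_order = tuple(m.header_i32(w) for w in (17, 18, 19))
    if sorted(axis_order) != [1, 2, 3]:
        raise MapFormatError(f"{path}: invalid axis correspondence {axis_order}")
    origin_words = tuple(m.header_float(w) for w in (50, 51, 52))
    nstart_crs = tuple(m.header_i32(w) for w in (5, 6, 7))

    # Transpose the data so in-memory axes are x,y,z (gemmi index order u,v,w).
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    data_xyz = np.array(m.grid, copy=True)

    nx, ny, nz = data_xyz.shape
    vx = cell.a / nx
    vy = cell.b / ny
    vz = cell.c / nz
    voxel = (vx, vy, vz)

    if any(abs(o) > 0 for o in origin_words):
        origin = origin_words
    else:
        # nstart is stored per column/row/section; permute to x,y,z.
        nstart_xyz = [0, 0, 0]
        for file_axis, xyz in enumerate(axis_order):
            nstart_xyz[xyz - 1] = nstart_crs[file_axis]
        origin = tuple(nstart_xyz[i] * voxel[i] for i in range(3))

    if not np.isfinite(data_xyz).all():
        raise MapFormatError(f"{path}: map contains non-finite voxel values")

    return VoxelGrid(
        data_xyz.transpose(2, 1, 0),
        voxel_size=voxel,
        origin=origin,
        axis_order=axis_order,
    )


def write_map(g: VoxelGrid, path: str | Path) -> None:
    """Write ``g`` as a mode-2 (float32) MRC2014 file with canonical axes."""
    path = Path(path)
    nx, ny, nz = g.shape_xyz
    grid = gemmi.FloatGrid(nx, ny, nz)
    vx, vy, vz = g.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0))
    np.asarray(grid)[...] = g.data.transpose(2, 1, 0)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for w, o in zip((50, 51, 52), g.origin):
        m.set_header_float(w, float(o))
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write map to {path}: {exc}") from exc


def resample_to_grid(
    g: VoxelGrid, target_voxel: float, order: int = 1
) -> VoxelGrid:
    """Resample onto an isotropic grid of ``target_voxel`` Å spacing.

    The physical extent is preserved to within one voxel and the origin is
    unchanged.  Interpolation is trilinear by default (``order=1``); higher
    spline orders are available through ``order``.  Points falling outside
    the source grid evaluate to 0 (solvent padding).
    """
    if not (np.isfinite(target_voxel) and target_voxel > 0):
        raise ValueError(f"target_voxel must be positive, got {target_voxel}")
    if any(n < 2 for n in g.data.shape):
        raise ValueError(f"cannot resample degenerate grid of shape {g.data.shape}")

    if all(abs(v - target_voxel) < 1e-9 for v in g.voxel_size):
        return g.copy()

    nz, ny, nx = g.data.shape
    vx, vy, vz = g.voxel_size
    new_nx = max(1, int(round(nx * vx / target_voxel)))
    new_ny = max(1, int(round(ny * vy / target_voxel)))
    new_nz = max(1, int(round(nz * vz / target_voxel)))

    # Fractional source indices of the new grid points, per axis (z, y, x).
    zc = np.arange(new_nz) * (target_voxel / vz)
    yc = np.arange(new_ny) * (target_voxel / vy)
    xc = np.arange(new_nx) * (target_voxel / vx)
    coords = np.meshgrid(zc, yc, xc, indexing="ij")
    out = ndimage.map_coordinates(
        g.data.astype(np.float64),
        np.stack([c.ravel() for c in coords]),
        order=order,
        mode="constant",
        cval=0.0,
    ).reshape(new_nz, new_ny, new_nx)
    return VoxelGrid(
        out.astype(np.float32),
        voxel_size=(target_voxel,) * 3,
        origin=g.origin,
        axis_order=g.axis_order,
    )
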