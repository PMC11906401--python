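"""Map-model validation metrics.

Fourier shell correlation (FSC) between two maps on identical grids is the
per-shell normalized cross-spectrum

    FSC(s) = Re( sum_shell F_a conj(F_b) )
             / sqrt( sum_shell |F_a|^2 * sum_shell |F_b|^2 )

with shells one Fourier voxel wide (radial index rounded to the nearest
integer).  The resolution at a threshold (0.143 or 0.5) is the reciprocal
of the spatial frequency at the first downward crossing, linearly
interpolated between the bracketing shells; if the curve never crosses,
the Nyquist-limit resolution is returned with a flag.

Real-space validation uses three Pearson correlations between the
experimental and model-calculated maps: over the whole box (CC_box), over
a molecular mask around the atoms (CC_mask), and over the union of each
map's N highest-density voxels where N is the mask size (CC_peaks).
The model-calculated map here is this package's own reference-Gaussian
simulation; values are therefore internally consistent but not expected
to agree digit-for-digit with external tools whose mask construction and
map synthesis differ.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .grid import VoxelGrid
from .structure import AtomicStructure

__all__ = [
    "FscCurve",
    "ResolutionEstimate",
    "CcReport",
    "fsc",
    "resolution_at",
    "molecular_mask",
    "cc_scores",
]

DEFAULT_MASK_RADIUS = 3.0  # Å


@dataclasses.dataclass(frozen=True)
class FscCurve:
    """Per-shell correlation vs spatial frequency (1/Å)."""

    shell_centers: np.ndarray
    correlations: np.ndarray
    shell_width: float
    nyquist: float

    def __post_init__(self):
        object.__setattr__(self, "shell_centers", np.asarray(self.shell_centers, dtype=float))
        object.__setattr__(self, "correlations", np.asarray(self.correlations, dtype=float))
        if len(self.shell_centers) != len(self.correlations):
            raise ValueError("shell_centers and correlations differ in length")


@dataclasses.dataclass(frozen=True)
class ResolutionEstimate:
    resolution: float  # Å
    threshold: float
    limit_reached: bool  # curve never crossed the threshold before Nyquist

    def __float__(self) -> float:
        return self.resolution


@dataclasses.dataclass(frozen=True)
class CcReport:
    cc_box: float
    cc_mask: float
    cc_peaks: float
    degenerate: bool = False  # a constant region made a correlation undefined


def _check_same_geometry(a: VoxelGrid, b: VoxelGrid) -> None:
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if any(abs(x - y) > 1e-6 for x, y in zip(a.voxel_size, b.voxel_size)):
        raise ValueError(f"voxel size mismatch: {a.voxel_size} vs {b.voxel_size}")


def fsc(a: VoxelGrid, b: VoxelGrid) -> FscCurve:
    """Fourier shell correlation between two maps of identical geometry."""
    _check_same_geometry(a, b)
    fa = np.fft.fftn(a.data.astype(np.float64))
    fb = np.fft.fftn(b.data.astype(np.float64))

    # physical spatial frequencies (1/Å) per axis; shells one Fourier voxel
    # of the largest box dimension wide
    nz, ny, nx = a.data.shape
    vx, vy, vz = a.voxel_size
    fx = np.fft.fftfreq(nx, d=vx)
    fy = np.fft.fftfreq(ny, d=vy)
    fz = np.fft.fftfreq(nz, d=vz)
    s2 = (
        fz[:, None, None] ** 2 + fy[None, :, None] ** 2 + fx[None, None, :] ** 2
    )
    s = np.sqrt(s2)
    ds = 1.0 / max(nx * vx, ny * vy, nz * vz)
    shell_idx = np.rint(s / ds).astype(np.int64)

    n_shells = int(shell_idx.max()) + 1
    cross = np.bincount(shell_idx.ravel(), weights=(fa * np.conj(fb)).real.ravel(), minlength=n_shells)
    pa = np.bincount(shell_idx.ravel(), weights=(np.abs(fa) ** 2).ravel(), minlength=n_shells)
    pb = np.bincount(shell_idx.ravel(), weights=(np.abs(fb) ** 2).ravel(), minlength=n_shells)

    denom = np.sqrt(pa * pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cross / denom, 0.0)
    corr = np.clip(corr, -1.0, 1.0)

    nyquist = 1.0 / (2.0 * max(a.voxel_size))
    centers = np.arange(n_shells) * ds
    keep = centers <= nyquist + 0.5 * ds
    return FscCurve(centers[keep], corr[keep], shell_width=ds, nyquist=nyquist)


def resolution_at(curve: FscCurve, threshold: float = 0.143) -> ResolutionEstimate:
    """Resolution (Å) at the curve's first downward threshold crossing.

    The DC shell is excluded from the search.  Linear interpolation is used
    between the bracketing shells.  If the curve stays above the threshold
    out to Nyquist the Nyquist-limit resolution is returned, flagged.
    """
    s = curve.shell_centers
    c = curve.correlations
    if len(s) == 0:
        raise ValueError("empty FSC curve")
    for i in range(1, len(c) - 1):
        if c[i] >= threshold and c[i + 1] < threshold:
            f = s[i] + (s[i + 1] - s[i]) * (c[i] - threshold) / (c[i] - c[i + 1])
            return ResolutionEstimate(1.0 / f, threshold, limit_reached=False)
    # never above then below: either always above (limit) or below from the start
    if len(c) > 1 and c[1] < threshold:
        return ResolutionEstimate(1.0 / s[1], threshold, limit_reached=False)
    return ResolutionEstimate(1.0 / curve.nyquist, threshold, limit_reached=True)


def molecular_mask(
    s: AtomicStructure, template: VoxelGrid, radius: float = DEFAULT_MASK_RADIUS
) -> np.ndarray:
    """Binary grid: a voxel is inside iff within ``radius`` Å of any atom."""
    if radius <= 0:
        raise ValueError(f"mask radius must be positive, got {radius}")
    if len(s) == 0:
        raise ValueError("cannot build a mask from zero atoms")
    nz, ny, nx = template.data.shape
    vx, vy, vz = template.voxel_size
    ox, oy, oz = template.origin
    xs, ys, zs = template.index_coords()
    mask = np.zeros((nz, ny, nx), dtype=bool)
    r2 = radius * radius
    for px, py, pz in s.coords:
        ix_lo = max(0, int(math.ceil((px - radius - ox) / vx)))
        ix_hi = min(nx - 1, int(math.floor((px + radius - ox) / vx)))
        iy_lo = max(0, int(math.ceil((py - radius - oy) / vy)))
        iy_hi = min(ny - 1, int(math.floor((py + radius - oy) / vy)))
        iz_lo = max(0, int(math.ceil((pz - radius - oz) / vz)))
        iz_hi = min(nz - 1, int(math.floor((pz + radius - oz) / vz)))
        if ix_lo > ix_hi or iy_lo > iy_hi or iz_lo > iz_hi:
            continue
        dx2 = (xs[ix_lo : ix_hi + 1] - px) ** 2
        dy2 = (ys[iy_lo : iy_hi + 1] - py) ** 2
        dz2 = (zs[iz_lo : iz_hi + 1] - pz) ** 2
        inside = (
            dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
        ) <= r2
        mask[iz_lo : iz_hi + 1, iy_lo : iy_hi + 1, ix_lo : ix_hi + 1] |= inside
    return mask


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt((a * a).sum())
    nb = np.sqrt((b * b).sum())
    if na == 0 or nb == 0:
        return 0.0, True
    return float(np.clip((a * b).sum() / (na * nb), -1.0, 1.0)), False


def cc_scores(exp: VoxelGrid, model_map: VoxelGrid, mask: np.ndarray) -> CcReport:
    """CC_box, CC_mask and CC_peaks between an experimental map and a
    model-calculated map.

    CC_peaks correlates over the union of the N highest-density voxels of
    each map, where N is the number of voxels inside the molecular mask.
    A zero-variance region yields a flagged report (correlation set to 0)
    rather than NaN.
    """
    _check_same_geometry(exp, model_map)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != exp.data.shape:
        raise ValueError(f"mask shape {mask.shape} does not match maps {exp.data.shape}")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("molecular mask is empty")

    cc_box, d1 = _pearson(exp.data, model_map.data)
    cc_mask_val, d2 = _pearson(exp.data[mask], model_map.data[mask])

    def top_n(a: np.ndarray) -> np.ndarray:
        flat = a.ravel()
        return np.argpartition(flat, -n_mask)[-n_mask:]

    union = np.union1d(top_n(exp.data), top_n(model_map.data))
    cc_peaks_val, d3 = _pearson(exp.data.ravel()[union], model_map.data.ravel()[union])
    return CcReport(cc_box, cc_mask_val, cc_peaks_val, degenerate=d1 or d2 or d3)
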