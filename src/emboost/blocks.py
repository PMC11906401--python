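"""Map normalization and overlapping-block decomposition.

Large maps are processed in overlapping cubic blocks: 64³ blocks with
stride 50 for training (randomly cropped to 48³ on the fly) and 48³ blocks
with stride 38 for validation/inference.  Blocks whose target cube is
empty carry no signal and are dropped from training.  Predicted blocks are
reassembled by averaging every block's prediction at each voxel
(coverage-count weighting), which makes extract→assemble an exact
round trip.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np

from .grid import VoxelGrid

__all__ = [
    "BlockLayout",
    "BlockPair",
    "AugmentRecord",
    "normalize_percentile",
    "make_layout",
    "extract_blocks",
    "filter_nonempty",
    "augment",
    "invert_augment",
    "assemble_blocks",
    "pad_to_block",
]

TRAIN_BLOCK = 64
TRAIN_STRIDE = 50
EVAL_BLOCK = 48
EVAL_STRIDE = 38
NORM_PERCENTILE = 99.999


@dataclasses.dataclass(frozen=True)
class BlockLayout:
    """Deterministic decomposition of a grid into overlapping cubes."""

    block_size: int
    stride: int
    positions: tuple[tuple[int, int, int], ...]
    grid_shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.positions)


@dataclasses.dataclass
class BlockPair:
    """A matched (input, target) density cube at one block position."""

    input_block: np.ndarray
    target_block: np.ndarray
    position: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.input_block = np.asarray(self.input_block, dtype=np.float32)
        self.target_block = np.asarray(self.target_block, dtype=np.float32)
        if self.input_block.shape != self.target_block.shape:
            raise ValueError(
                f"input/target shape mismatch: {self.input_block.shape} vs "
                f"{self.target_block.shape}"
            )


@dataclasses.dataclass(frozen=True)
class AugmentRecord:
    """The random transform applied to a training pair (crop → rot90 → flips)."""

    crop_offset: tuple[int, int, int]
    rot_axes: tuple[int, int]
    rot_k: int
    flips: tuple[bool, bool, bool]


def normalize_percentile(
    g: VoxelGrid, pct: float = NORM_PERCENTILE
) -> tuple[VoxelGrid, float]:
    """Scale ``g`` to [0, 1] by its ``pct``-th percentile density.

    Values above the percentile clamp to 1 and negative densities clamp
    to 0.  Returns the normalized grid and the scale (the percentile
    value) for provenance.
    """
    scale = float(np.percentile(g.data, pct))
    if not (np.isfinite(scale) and scale > 0):
        raise ValueError(
            f"{pct}th percentile is {scale}; map must contain positive density"
        )
    out = np.clip(g.data / scale, 0.0, 1.0).astype(np.float32)
    return g.with_data(out), scale


def _axis_starts(dim: int, block: int, stride: int) -> list[int]:
    starts = list(range(0, dim - block + 1, stride))
    last = dim - block
    if starts[-1] != last:
        starts.append(last)
    return starts


def make_layout(
    shape: Sequence[int], block_size: int, stride: int
) -> BlockLayout:
    """Block start positions: 0, stride, 2·stride, … with the final block
    clamped to ``dim - block_size`` so every voxel is covered."""
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3:
        raise ValueError(f"expected a 3D shape, got {shape}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if block_size < 1:
        raise ValueError(f"block_size must be >= 1, got {block_size}")
    if any(n < block_size for n in shape):
        raise ValueError(
            f"grid shape {shape} smaller than block size {block_size}; "
            "pad the grid first (see pad_to_block)"
        )
    per_axis = [_axis_starts(n, block_size, stride) for n in shape]
    positions = tuple(itertools.product(*per_axis))
    return BlockLayout(block_size, stride, positions, shape)


def pad_to_block(
    g: VoxelGrid, block_size: int
) -> tuple[VoxelGrid, tuple[tuple[int, int], ...]]:
    """Zero-pad ``g`` symmetrically so every dimension is >= ``block_size``.

    Returns the padded grid and the per-axis (before, after) padding, for
    cropping after assembly.  The origin shifts by the leading padding so
    physical coordinates are preserved.
    """
    pads = []
    for n in g.data.shape:
        missing = max(0, block_size - n)
        before = missing // 2
        pads.append((before, missing - before))
    pads = tuple(pads)
    if all(p == (0, 0) for p in pads):
        return g, pads
    data = np.pad(g.data, pads, mode="constant")
    vx, vy, vz = g.voxel_size
    ox, oy, oz = g.origin
    origin = (ox - pads[2][0] * vx, oy - pads[1][0] * vy, oz - pads[0][0] * vz)
    return VoxelGrid(data, g.voxel_size, origin, g.axis_order), pads


def extract_blocks(g: VoxelGrid, layout: BlockLayout) -> list[np.ndarray]:
    """Copy out the sub-cube at every layout position."""
    if layout.grid_shape != g.data.shape:
        raise ValueError(
            f"layout was built for shape {layout.grid_shape}, grid has {g.data.shape}"
        )
    b = layout.block_size
    return [
        g.data[z : z + b, y : y + b, x : x + b].copy()
        for (z, y, x) in layout.positions
    ]


def filter_nonempty(
    pairs: Iterable[BlockPair], min_occupancy: float = 0.0
) -> list[BlockPair]:
    """Keep pairs whose target cube has more than ``min_occupancy`` fraction
    of voxels above zero (the default keeps any block with signal)."""
    kept = []
    for p in pairs:
        frac = float(np.count_nonzero(p.target_block > 0)) / p.target_block.size
        if frac > min_occupancy:
            kept.append(p)
    return kept


def augment(
    pair: BlockPair,
    rng: np.random.Generator,
    crop_size: int = EVAL_BLOCK,
) -> tuple[BlockPair, AugmentRecord]:
    """Random crop + 90°-multiple rotation + axis flips, identically applied
    to input and target.

    Training pairs must be strictly larger than ``crop_size`` (64³ in the
    standard pipeline); augmenting an eval-sized pair is an error because
    there is nothing to crop.
    """
    shape = pair.input_block.shape
    if any(n < crop_size for n in shape):
        raise ValueError(f"block shape {shape} smaller than crop size {crop_size}")
    if all(n == crop_size for n in shape):
        raise ValueError(
            f"block shape {shape} equals the crop size; eval blocks are not augmented"
        )
    off = tuple(int(rng.integers(0, n - crop_size + 1)) for n in shape)
    axes_choices = ((0, 1), (0, 2), (1, 2))
    rot_axes = axes_choices[int(rng.integers(0, 3))]
    rot_k = int(rng.integers(0, 4))
    flips = tuple(bool(f) for f in rng.random(3) < 0.5)
    rec = AugmentRecord(off, rot_axes, rot_k, flips)

    def apply(a: np.ndarray) -> np.ndarray:
        a = a[
            off[0] : off[0] + crop_size,
            off[1] : off[1] + crop_size,
            off[2] : off[2] + crop_size,
        ]
        a = np.rot90(a, k=rot_k, axes=rot_axes)
        for ax, f in enumerate(flips):
            if f:
                a = np.flip(a, axis=ax)
        return np.ascontiguousarray(a)

    return BlockPair(apply(pair.input_block), apply(pair.target_block), pair.position), rec


def invert_augment(block: np.ndarray, rec: AugmentRecord) -> np.ndarray:
    """Undo the rotation/flips of ``rec``, recovering the pre-augmentation crop."""
    a = block
    for ax, f in enumerate(rec.flips):
        if f:
            a = np.flip(a, axis=ax)
    a = np.rot90(a, k=-rec.rot_k, axes=rec.rot_axes)
    return np.ascontiguousarray(a)


def assemble_blocks(
    blocks: Sequence[np.ndarray],
    layout: BlockLayout,
    like: VoxelGrid | None = None,
) -> VoxelGrid:
    """Reassemble per-block predictions into a full map.

    Each voxel takes the mean of all block values covering it.  Sums and
    counts accumulate in float64, so identical overlapping values are
    recovered bit-exactly in float32 (the extract→assemble round trip is
    the identity).  Metadata is copied from ``like`` when given.
    """
    if len(blocks) != len(layout.positions):
        raise ValueError(
            f"got {len(blocks)} blocks for {len(layout.positions)} layout positions"
        )
    b = layout.block_size
    acc = np.zeros(layout.grid_shape, dtype=np.float64)
    cnt = np.zeros(layout.grid_shape, dtype=np.float64)
    for blk, (z, y, x) in zip(blocks, layout.positions):
        blk = np.asarray(blk)
        if blk.shape != (b, b, b):
            raise ValueError(f"block at {(z, y, x)} has shape {blk.shape}, expected {(b, b, b)}")
        acc[z : z + b, y : y + b, x : x + b] += blk.astype(np.float64)
        cnt[z : z + b, y : y + b, x : x + b] += 1.0
    if (cnt == 0).any():
        raise ValueError("layout does not cover every voxel")
    data = (acc / cnt).astype(np.float32)
    if like is not None:
        return VoxelGrid(data, like.voxel_size, like.origin, like.axis_order)
    return VoxelGrid(data)
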