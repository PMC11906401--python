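"""Full-map inference.

Pipeline: resample to 1 Å → percentile-normalize to [0, 1] → pad (if the
map is smaller than one block) → decompose into 48³ blocks at stride 38 →
batch the blocks through the network in eval mode → reassemble with mean
overlap blending → restore the source metadata.  The enhanced map stays in
the normalized density space the network was trained in; the input's
normalization scale is returned for provenance.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .blocks import (
    EVAL_BLOCK,
    EVAL_STRIDE,
    assemble_blocks,
    extract_blocks,
    make_layout,
    normalize_percentile,
    pad_to_block,
)
from .grid import VoxelGrid, resample_to_grid
from .model import EnhancerModel

__all__ = ["EnhanceResult", "enhance_map"]

TARGET_VOXEL = 1.0  # Å


@dataclasses.dataclass
class EnhanceResult:
    map: VoxelGrid
    normalization_scale: float
    n_blocks: int


def enhance_map(
    g: VoxelGrid,
    model: EnhancerModel,
    batch_size: int = 8,
    stride: int = EVAL_STRIDE,
    restore_voxel: bool = False,
) -> EnhanceResult:
    """Enhance a full density map with a trained model.

    ``restore_voxel`` resamples the output back to the input's native voxel
    size (by default the result stays on the 1 Å working grid).
    """
    if g.data.size == 0 or min(g.data.shape) < 1:
        raise ValueError("empty or degenerate input map")
    block = model.config.input_size
    if stride < 1 or stride > block:
        raise ValueError(f"stride must be in [1, {block}], got {stride}")

    native_voxel = g.voxel_size
    work = resample_to_grid(g, TARGET_VOXEL) if any(
        abs(v - TARGET_VOXEL) > 1e-6 for v in g.voxel_size
    ) else g
    work, scale = normalize_percentile(work)
    padded, pads = pad_to_block(work, block)

    layout = make_layout(padded.data.shape, block, stride)
    blocks = extract_blocks(padded, layout)
    out_blocks = model.enhance_blocks(np.stack(blocks), batch_size=batch_size)
    if not np.isfinite(out_blocks).all():
        bad = [
            layout.positions[i]
            for i in range(len(out_blocks))
            if not np.isfinite(out_blocks[i]).all()
        ]
        raise FloatingPointError(f"non-finite model output in blocks at {bad[:5]}")

    assembled = assemble_blocks(list(out_blocks), layout, like=padded)
    if any(p != (0, 0) for p in pads):
        sl = tuple(
            slice(b, n - a if a else None)
            for (b, a), n in zip(pads, assembled.data.shape)
        )
        assembled = VoxelGrid(
            assembled.data[sl], work.voxel_size, work.origin, work.axis_order
        )
    if restore_voxel and any(abs(v - TARGET_VOXEL) > 1e-6 for v in native_voxel):
        # note: restores an isotropic grid at the native mean spacing
        assembled = resample_to_grid(assembled, float(np.mean(native_voxel)))
    return EnhanceResult(assembled, normalization_scale=scale, n_blocks=len(layout))
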