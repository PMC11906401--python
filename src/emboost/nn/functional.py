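"""Volumetric neural-network primitives with custom gradients.

3D convolution gathers one patch matrix per kernel offset (27 strided
slice copies for a 3³ kernel) and contracts it with the kernel by a single
matmul; the input gradient scatters back through the same 27 disjoint
strided slices, so no indexed scatter is needed.  The stride-2 transposed
convolution used for decoder upsampling has kernel size equal to its
stride and reduces to an einsum (exact 2× voxel doubling, no overlap).
"""

from __future__ import annotations

import itertools

import numpy as np

from .tensor import Tensor, is_grad_enabled

__all__ = ["conv3d", "conv_transpose3d_s2", "dropout"]


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def _gather_cols(xp: np.ndarray, k: int, stride: int, out_sp: tuple[int, int, int]) -> np.ndarray:
    """(B, C, Dp, Hp, Wp) padded input → (B, C, k³, Do, Ho, Wo) patch tensor."""
    b, c = xp.shape[:2]
    do, ho, wo = out_sp
    cols = np.empty((b, c, k**3, do, ho, wo), dtype=xp.dtype)
    for i, (kd, kh, kw) in enumerate(itertools.product(range(k), repeat=3)):
        cols[:, :, i] = xp[
            :, :,
            kd : kd + do * stride : stride,
            kh : kh + ho * stride : stride,
            kw : kw + wo * stride : stride,
        ]
    return cols


def _scatter_cols(
    gcols: np.ndarray, in_sp: tuple[int, int, int], k: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of :func:`_gather_cols`: accumulate patches into the input."""
    b, c = gcols.shape[:2]
    do, ho, wo = gcols.shape[3:]
    dp, hp, wp = (n + 2 * pad for n in in_sp)
    xg = np.zeros((b, c, dp, hp, wp), dtype=np.float32)
    for i, (kd, kh, kw) in enumerate(itertools.product(range(k), repeat=3)):
        xg[
            :, :,
            kd : kd + do * stride : stride,
            kh : kh + ho * stride : stride,
            kw : kw + wo * stride : stride,
        ] += gcols[:, :, i]
    if pad:
        xg = np.ascontiguousarray(xg[:, :, pad:-pad, pad:-pad, pad:-pad])
    return xg


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """3D cross-correlation of (B, Cin, D, H, W) with (Cout, Cin, k, k, k)."""
    cout, cin, k, _, _ = w.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv3d: input has {x.shape[1]} channels, kernel expects {cin}")
    in_sp = x.shape[2:]
    out_sp = tuple(_out_size(n, k, stride, pad) for n in in_sp)
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3) if pad else x.data
    cols = _gather_cols(xp, k, stride, out_sp)
    bsz = x.shape[0]
    ell = int(np.prod(out_sp))
    w_flat = w.data.reshape(cout, cin * k**3)
    out_data = np.matmul(w_flat, cols.reshape(bsz, cin * k**3, ell)).reshape(
        bsz, cout, *out_sp
    )
    if b is not None:
        out_data += b.data.reshape(1, cout, 1, 1, 1)
    del cols, xp  # regathered in backward; keeping them would hold the peak

    parents = [p for p in (x, w, b) if p is not None and p.requires_grad]
    req = is_grad_enabled() and bool(parents)
    if not req:
        return Tensor(out_data)

    def backward(g):
        g_flat = g.reshape(bsz, cout, ell)
        if w.requires_grad:
            xp_b = (
                np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * 3) if pad else x.data
            )
            cols_b = _gather_cols(xp_b, k, stride, out_sp).reshape(bsz, cin * k**3, ell)
            gw = np.einsum("bol,bfl->of", g_flat, cols_b, optimize=True)
            w._accumulate(gw.reshape(w.shape))
            del cols_b
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gcols = np.matmul(w_flat.T, g_flat)
            x._accumulate(
                _scatter_cols(
                    gcols.reshape(bsz, cin, k**3, *out_sp), in_sp, k, stride, pad
                )
            )

    return Tensor(out_data, requires_grad=True, _parents=tuple(parents), _backward=backward)


def conv_transpose3d_s2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed conv, kernel 2 / stride 2: exact spatial doubling.

    ``x`` is (B, Cin, D, H, W); ``w`` is (Cin, Cout, 2, 2, 2); output is
    (B, Cout, 2D, 2H, 2W).  Kernel cells do not overlap, so forward and
    backward are plain einsums.
    """
    bsz, cin, d, h, wd = x.shape
    if w.shape[0] != cin or w.shape[2:] != (2, 2, 2):
        raise ValueError(
            f"conv_transpose3d_s2: kernel shape {w.shape} incompatible with input {x.shape}"
        )
    cout = w.shape[1]
    z = np.einsum("bcdhw,copqr->bodphqwr", x.data, w.data, optimize=True)
    out_data = z.reshape(bsz, cout, 2 * d, 2 * h, 2 * wd)
    if b is not None:
        out_data += b.data.reshape(1, cout, 1, 1, 1)

    parents = [p for p in (x, w, b) if p is not None and p.requires_grad]
    req = is_grad_enabled() and bool(parents)
    if not req:
        return Tensor(out_data)

    def backward(g):
        gz = g.reshape(bsz, cout, d, 2, h, 2, wd, 2)
        if x.requires_grad:
            x._accumulate(np.einsum("bodphqwr,copqr->bcdhw", gz, w.data, optimize=True))
        if w.requires_grad:
            w._accumulate(np.einsum("bcdhw,bodphqwr->copqr", x.data, gz, optimize=True))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))

    return Tensor(out_data, requires_grad=True, _parents=tuple(parents), _backward=backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout: zero with probability ``p``, rescale by 1/(1-p)."""
    if not training or p <= 0:
        return x
    keep = (rng.random(x.shape, dtype=np.float32) >= p).astype(np.float32) / (1.0 - p)
    return x * Tensor(keep)
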