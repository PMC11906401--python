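"""The enhancement network and its loss.

Architecture: a 3D transformer U-Net in the UNETR++ lineage.  Four encoder
stages (stride-2 downsampling convolution + group normalization + three
transformer layers) halve the spatial size 48³→24³→12³→6³→3³ while widening
channels; four decoder stages (stride-2 transposed convolution + skip
concatenation + three transformer layers) mirror them back to 48³.  Each
transformer layer adds a learned positional embedding and applies efficient
paired attention (EPA) — a spatial branch whose keys/values are projected
to a small fixed number of tokens before the dot product, and a channel
branch, with the query/key mapping weights shared between the two — plus a
3³ convolution with leaky-rectifier activation, batch normalization and
dropout.  A parallel residual convolution branch (ConvRes) processes the
raw input block; its output is concatenated with the last decoder's output
and fused by a final convolution back to one 48³ channel.

The training loss is a masked mean squared error: voxels that are zero in
both the network output and the simulated target are excluded, and the
squared error is averaged over the remaining voxels (defined as 0 when no
voxel survives masking).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "EnhancerModel",
    "EpaAttention",
    "TransformerLayer3d",
    "ConvRes",
    "masked_mse",
    "masked_mse_loss",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA = 1


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the enhancement network.

    ``channels`` are the per-stage widths (stage count is their length);
    each stage halves the spatial size, so ``input_size`` must be divisible
    by 2**stages.  ``epa_proj_dim`` is the token count the spatial-attention
    keys/values are projected to (clamped to the stage's token count).
    """

    input_size: int = 48
    channels: tuple[int, ...] = (32, 64, 128, 256)
    transformer_layers_per_stage: int = 3
    num_heads: int = 4
    epa_proj_dim: int = 64
    dropout_p: float = 0.1
    leaky_slope: float = 0.01
    conv_res_channels: int | None = None
    groupnorm_groups: int = 4
    residual_zero_init: bool = True
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(int(c) for c in self.channels))
        stages = len(self.channels)
        if self.input_size % (2**stages):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{stages} stages"
            )
        for c in self.channels:
            if c % self.num_heads:
                raise ValueError(f"channel width {c} not divisible by {self.num_heads} heads")
            if c % self.groupnorm_groups:
                raise ValueError(f"channel width {c} not divisible by {self.groupnorm_groups} groups")

    @property
    def stages(self) -> int:
        return len(self.channels)

    @property
    def stage_sizes(self) -> tuple[int, ...]:
        """Spatial edge length after each encoder stage."""
        return tuple(self.input_size // 2 ** (i + 1) for i in range(self.stages))

    def conv_res_width(self) -> int:
        if self.conv_res_channels is not None:
            return self.conv_res_channels
        return max(4, self.channels[0] // 2)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{k: tuple(v) if k == "channels" else v for k, v in d.items()})


class EpaAttention(nn.Module):
    """Efficient paired attention: shared-QK spatial + channel branches.

    The query and key linear maps are shared between the branches.  The
    spatial branch projects keys and values from N tokens down to
    ``proj_dim`` tokens before the dot product; the channel branch attends
    over the C×C channel Gram matrix.  Branch outputs pass through their
    own output projections, are summed, and mixed by a 1³ convolution.
    """

    def __init__(
        self,
        channels: int,
        n_tokens: int,
        num_heads: int,
        proj_dim: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        if channels % num_heads:
            raise ValueError(f"{channels} channels not divisible by {num_heads} heads")
        self.channels = channels
        self.n_tokens = n_tokens
        self.num_heads = num_heads
        self.head_dim = channels // num_heads
        p = min(proj_dim, n_tokens)
        self.proj_dim = p
        self.q = nn.Linear(channels, channels, rng, bias=False)
        self.k = nn.Linear(channels, channels, rng, bias=False)  # shared between branches
        self.v_spatial = nn.Linear(channels, channels, rng, bias=False)
        self.v_channel = nn.Linear(channels, channels, rng, bias=False)
        self.token_proj_k = nn.Linear(n_tokens, p, rng, bias=False)
        self.token_proj_v = nn.Linear(n_tokens, p, rng, bias=False)
        self.out_spatial = nn.Linear(channels, channels, rng)
        self.out_channel = nn.Linear(channels, channels, rng)
        self.mix = nn.Conv3d(channels, channels, 1, rng)

    def _split_heads(self, t: Tensor, b: int, n: int) -> Tensor:
        return t.reshape(b, n, self.num_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        n = int(np.prod(spatial))
        if c != self.channels or n != self.n_tokens:
            raise ValueError(
                f"EPA built for {self.channels} channels / {self.n_tokens} tokens, "
                f"got {c} / {n}"
            )
        t = x.reshape(b, c, n).swapaxes(1, 2)  # (B, N, C)
        qh = self._split_heads(self.q(t), b, n)          # (B, h, N, d)
        kh = self._split_heads(self.k(t), b, n)
        vsh = self._split_heads(self.v_spatial(t), b, n)
        vch = self._split_heads(self.v_channel(t), b, n)

        # spatial branch: project K, V over the token axis to proj_dim tokens
        kp = self.token_proj_k(kh.transpose(0, 1, 3, 2))   # (B, h, d, p)
        vp = self.token_proj_v(vsh.transpose(0, 1, 3, 2))  # (B, h, d, p)
        scores_s = (qh @ kp) * (1.0 / math.sqrt(self.head_dim))  # (B, h, N, p)
        out_s = scores_s.softmax(axis=-1) @ vp.transpose(0, 1, 3, 2)  # (B, h, N, d)

        # channel branch: attention over the d×d per-head channel Gram matrix
        scores_c = (qh.transpose(0, 1, 3, 2) @ kh) * (1.0 / math.sqrt(n))  # (B, h, d, d)
        out_c = vch @ scores_c.softmax(axis=-1).transpose(0, 1, 3, 2)      # (B, h, N, d)

        def merge(u: Tensor) -> Tensor:
            return u.transpose(0, 2, 1, 3).reshape(b, n, c)

        fused = self.out_spatial(merge(out_s)) + self.out_channel(merge(out_c))
        vol = fused.swapaxes(1, 2).reshape(b, c, *spatial)
        return self.mix(vol)


class TransformerLayer3d(nn.Module):
    """Positional embedding + EPA + convolutional mixing, both residual."""

    def __init__(
        self,
        channels: int,
        edge: int,
        num_heads: int,
        proj_dim: int,
        dropout_p: float,
        leaky_slope: float,
        rng: np.random.Generator,
        dropout_rng: np.random.Generator,
        zero_init: bool = True,
    ):
        super().__init__()
        pos = rng.normal(0.0, 0.02, size=(1, channels, edge, edge, edge))
        self.pos_embed = nn.Parameter(np.clip(pos, -0.04, 0.04).astype(np.float32))
        self.norm_attn = nn.BatchNorm3d(channels)
        self.epa = EpaAttention(channels, edge**3, num_heads, proj_dim, rng)
        self.drop_attn = nn.Dropout(dropout_p, dropout_rng)
        self.conv = nn.Conv3d(channels, channels, 3, rng)
        self.act = nn.LeakyReLU(leaky_slope)
        self.norm_conv = nn.BatchNorm3d(channels)
        self.drop_conv = nn.Dropout(dropout_p, dropout_rng)
        if zero_init:
            # identity-biased start: both residual branches contribute zero
            # until their output scales wake up, which stabilizes and speeds
            # optimization at small step budgets
            self.epa.mix.weight.data[...] = 0.0
            if self.epa.mix.bias is not None:
                self.epa.mix.bias.data[...] = 0.0
            self.norm_conv.weight.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        h = x + self.pos_embed
        h = h + self.drop_attn(self.epa(self.norm_attn(h)))
        z = self.drop_conv(self.norm_conv(self.act(self.conv(h))))
        return h + z


class _EncoderStage(nn.Module):
    def __init__(self, in_ch, out_ch, edge, cfg: ModelConfig, rng, drop_rng):
        super().__init__()
        self.down = nn.Conv3d(in_ch, out_ch, 3, rng, stride=2, pad=1)
        self.norm = nn.GroupNorm(cfg.groupnorm_groups, out_ch)
        self.layers = nn.ModuleList(
            TransformerLayer3d(
                out_ch, edge, cfg.num_heads, cfg.epa_proj_dim,
                cfg.dropout_p, cfg.leaky_slope, rng, drop_rng,
                zero_init=cfg.residual_zero_init,
            )
            for _ in range(cfg.transformer_layers_per_stage)
        )

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm(self.down(x))
        for layer in self.layers:
            h = layer(h)
        return h


class _DecoderStage(nn.Module):
    def __init__(self, in_ch, out_ch, skip_ch, edge, cfg: ModelConfig, rng, drop_rng):
        super().__init__()
        self.up = nn.ConvTranspose3d(in_ch, out_ch, rng)
        self.fuse = nn.Conv3d(out_ch + skip_ch, out_ch, 3, rng)
        self.layers = nn.ModuleList(
            TransformerLayer3d(
                out_ch, edge, cfg.num_heads, cfg.epa_proj_dim,
                cfg.dropout_p, cfg.leaky_slope, rng, drop_rng,
                zero_init=cfg.residual_zero_init,
            )
            for _ in range(cfg.transformer_layers_per_stage)
        )

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        h = self.up(x)
        h = self.fuse(nn.concatenate([h, skip], axis=1))
        for layer in self.layers:
            h = layer(h)
        return h


class ConvRes(nn.Module):
    """Parallel residual convolution branch on the raw input block."""

    def __init__(self, out_ch: int, cfg: ModelConfig, rng):
        super().__init__()
        g = math.gcd(cfg.groupnorm_groups, out_ch)
        self.conv1 = nn.Conv3d(1, out_ch, 3, rng)
        self.norm1 = nn.GroupNorm(g, out_ch)
        self.conv2 = nn.Conv3d(out_ch, out_ch, 3, rng)
        self.norm2 = nn.GroupNorm(g, out_ch)
        self.conv3 = nn.Conv3d(out_ch + 1, out_ch, 3, rng)
        self.norm3 = nn.GroupNorm(g, out_ch)
        self.act = nn.LeakyReLU(cfg.leaky_slope)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm2(self.conv2(self.norm1(self.conv1(x))))
        h = nn.concatenate([h, x], axis=1)  # residual connection to the input
        return self.act(self.norm3(self.conv3(h)))


class EnhancerModel(nn.Module):
    """48³ block in → 48³ enhanced block out."""

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        cfg = config or ModelConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed).spawn(1)[0]
        )
        drop_rng = self.dropout_rng
        ch = cfg.channels
        sizes = cfg.stage_sizes
        self.encoders = nn.ModuleList(
            _EncoderStage(1 if i == 0 else ch[i - 1], ch[i], sizes[i], cfg, rng, drop_rng)
            for i in range(cfg.stages)
        )
        # decoder i upsamples stage (stages-1-i) back toward the input size
        dec = []
        for i in range(cfg.stages - 1):
            dec.append(
                _DecoderStage(
                    ch[cfg.stages - 1 - i], ch[cfg.stages - 2 - i],
                    skip_ch=ch[cfg.stages - 2 - i],
                    edge=sizes[cfg.stages - 2 - i], cfg=cfg, rng=rng, drop_rng=drop_rng,
                )
            )
        # final decoder returns to full resolution; its skip is the raw input
        dec.append(
            _DecoderStage(ch[0], ch[0], skip_ch=1, edge=cfg.input_size, cfg=cfg, rng=rng, drop_rng=drop_rng)
        )
        self.decoders = nn.ModuleList(dec)
        cr = cfg.conv_res_width()
        self.conv_res = ConvRes(cr, cfg, rng)
        self.fusion = nn.Conv3d(ch[0] + cr, 1, 3, rng)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        s = self.config.input_size
        if x.ndim == 3:
            x = x.reshape(1, 1, *x.shape)
        if x.ndim == 4:
            x = x.reshape(x.shape[0], 1, *x.shape[1:])
        if x.ndim != 5 or x.shape[2:] != (s, s, s) or x.shape[1] != 1:
            raise ValueError(
                f"expected single-channel blocks of shape ({s}, {s}, {s}), got {x.shape}"
            )
        skips = []
        h = x
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
        d = skips[-1]
        for i, dec in enumerate(self.decoders[:-1]):
            d = dec(d, skips[-2 - i])
        d = self.decoders[-1](d, x)
        r = self.conv_res(x)
        return self.fusion(nn.concatenate([d, r], axis=1))

    def enhance_blocks(self, blocks: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Run blocks (n, 48, 48, 48) through the net in eval mode."""
        was_training = self.training
        self.eval()
        outs = []
        try:
            with nn.no_grad():
                for i in range(0, len(blocks), batch_size):
                    batch = np.asarray(blocks[i : i + batch_size], dtype=np.float32)
                    out = self.forward(batch)
                    outs.append(out.data[:, 0])
        finally:
            self.train(was_training)
        return np.concatenate(outs, axis=0)


def masked_mse(output: np.ndarray, target: np.ndarray, eps: float = 0.0) -> float:
    """Mean squared error over voxels not zero in both arrays.

    Voxels where ``|output| <= eps`` and ``|target| <= eps`` (exact zeros by
    default) are masked out; the squared error is averaged over the
    remaining N voxels.  Returns 0.0 when every voxel is masked.
    """
    output = np.asarray(output)
    target = np.asarray(target)
    if output.shape != target.shape:
        raise ValueError(f"shape mismatch: {output.shape} vs {target.shape}")
    mask = ~((np.abs(output) <= eps) & (np.abs(target) <= eps))
    n = int(mask.sum())
    if n == 0:
        return 0.0
    diff = output[mask].astype(np.float64) - target[mask].astype(np.float64)
    return float((diff * diff).mean())


def masked_mse_loss(output: Tensor, target: np.ndarray, eps: float = 0.0) -> Tensor:
    """Differentiable masked MSE (mask treated as a constant)."""
    target = np.asarray(target, dtype=np.float32)
    if output.shape != target.shape:
        raise ValueError(f"shape mismatch: {output.shape} vs {target.shape}")
    mask = ~((np.abs(output.data) <= eps) & (np.abs(target) <= eps))
    n = int(mask.sum())
    if n == 0:
        return output.sum() * 0.0
    m = Tensor(mask.astype(np.float32))
    diff = (output - Tensor(target)) * m
    return (diff * diff).sum() * (1.0 / n)


def save_checkpoint(model: EnhancerModel, path: str | Path, extra: dict | None = None) -> None:
    """Self-describing checkpoint: weights + config + metadata."""
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": model.config.to_dict(),
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez_compressed(
        str(path),
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **state,
    )


def load_checkpoint(path: str | Path) -> tuple[EnhancerModel, dict]:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = EnhancerModel(ModelConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    return model, meta["extra"]
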