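"""scikit-learn style front end for the whole enhancement workflow."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .blocks import (
    BlockPair,
    EVAL_BLOCK,
    EVAL_STRIDE,
    TRAIN_BLOCK,
    TRAIN_STRIDE,
    extract_blocks,
    filter_nonempty,
    make_layout,
    normalize_percentile,
    pad_to_block,
)
from .enhance import enhance_map
from .grid import VoxelGrid, read_map, resample_to_grid
from .model import EnhancerModel, ModelConfig, load_checkpoint
from .train import TrainConfig, train

__all__ = ["MapEnhancer", "pairs_from_maps", "pairs_from_dataset"]


def pairs_from_maps(
    degraded: VoxelGrid,
    ideal: VoxelGrid,
    mode: str = "train",
    min_occupancy: float = 0.0,
) -> list[BlockPair]:
    """Normalize a (degraded, ideal) map pair and cut it into block pairs.

    ``mode='train'`` uses 64³ blocks at stride 50 (cropped to 48³ during
    augmentation); ``mode='eval'`` uses 48³ blocks at stride 38.  Both maps
    are resampled to 1 Å and normalized to [0, 1] by their own 99.999th
    percentile; empty target blocks are dropped.
    """
    if mode == "train":
        block, stride = TRAIN_BLOCK, TRAIN_STRIDE
    elif mode == "eval":
        block, stride = EVAL_BLOCK, EVAL_STRIDE
    else:
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    out = []
    x = resample_to_grid(degraded, 1.0) if any(abs(v - 1.0) > 1e-6 for v in degraded.voxel_size) else degraded
    y = resample_to_grid(ideal, 1.0) if any(abs(v - 1.0) > 1e-6 for v in ideal.voxel_size) else ideal
    x, _ = normalize_percentile(x)
    y, _ = normalize_percentile(y)
    x, _ = pad_to_block(x, block)
    y, _ = pad_to_block(y, block)
    if x.data.shape != y.data.shape:
        raise ValueError(
            f"degraded/ideal shapes differ after resampling: {x.data.shape} vs {y.data.shape}"
        )
    layout = make_layout(x.data.shape, block, stride)
    xb = extract_blocks(x, layout)
    yb = extract_blocks(y, layout)
    pairs = [BlockPair(a, b, pos) for a, b, pos in zip(xb, yb, layout.positions)]
    return filter_nonempty(pairs, min_occupancy)


def pairs_from_dataset(manifest: dict, mode: str = "train") -> list[BlockPair]:
    """Block pairs from a fixture-dataset manifest (see fixtures.make_dataset)."""
    root = Path(manifest["root"])
    pairs: list[BlockPair] = []
    for entry in manifest["entries"]:
        degraded = read_map(root / entry["input"])
        ideal = read_map(root / entry["target"])
        pairs.extend(pairs_from_maps(degraded, ideal, mode=mode))
    return pairs


class MapEnhancer(BaseEstimator, TransformerMixin):
    """Density-map enhancer with a fit/transform interface.

    ``fit`` trains the transformer U-Net on (degraded, ideal) block pairs;
    ``transform`` enhances full maps.  All network and optimization
    hyperparameters are constructor parameters so the estimator composes
    with scikit-learn model selection.

    Parameters mirror :class:`~emboost.model.ModelConfig` and
    :class:`~emboost.train.TrainConfig`; fitted state lives in ``model_``
    and ``train_state_``.
    """

    def __init__(
        self,
        input_size: int = EVAL_BLOCK,
        channels: tuple[int, ...] = (32, 64, 128, 256),
        num_heads: int = 4,
        epa_proj_dim: int = 64,
        transformer_layers_per_stage: int = 3,
        dropout_p: float = 0.1,
        batch_size: int = 64,
        initial_lr: float = 5e-4,
        min_lr: float = 1e-5,
        lr_halving_patience: int = 4,
        validations_per_epoch: int = 4,
        max_epochs: int = 10,
        inference_batch_size: int = 8,
        stride: int = EVAL_STRIDE,
        seed: int = 0,
    ):
        self.input_size = input_size
        self.channels = channels
        self.num_heads = num_heads
        self.epa_proj_dim = epa_proj_dim
        self.transformer_layers_per_stage = transformer_layers_per_stage
        self.dropout_p = dropout_p
        self.batch_size = batch_size
        self.initial_lr = initial_lr
        self.min_lr = min_lr
        self.lr_halving_patience = lr_halving_patience
        self.validations_per_epoch = validations_per_epoch
        self.max_epochs = max_epochs
        self.inference_batch_size = inference_batch_size
        self.stride = stride
        self.seed = seed

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            input_size=self.input_size,
            channels=tuple(self.channels),
            num_heads=self.num_heads,
            epa_proj_dim=self.epa_proj_dim,
            transformer_layers_per_stage=self.transformer_layers_per_stage,
            dropout_p=self.dropout_p,
            seed=self.seed,
        )

    def fit(
        self,
        X: Sequence[BlockPair],
        y=None,
        val_pairs: Sequence[BlockPair] | None = None,
        run_dir: str | None = None,
    ) -> "MapEnhancer":
        """Train on 64³ block pairs.

        ``val_pairs`` (48³ eval pairs) drive the plateau schedule; when not
        given, a deterministic 20% split of ``X`` is center-cropped to 48³
        and used for validation.
        """
        pairs = list(X)
        if val_pairs is None:
            rng = np.random.default_rng(self.seed)
            idx = rng.permutation(len(pairs))
            n_val = max(1, len(pairs) // 5)
            val_src = [pairs[i] for i in idx[:n_val]]
            pairs = [pairs[i] for i in idx[n_val:]]
            val_pairs = [self._center_crop(p, self.input_size) for p in val_src]
        cfg = TrainConfig(
            batch_size=self.batch_size,
            initial_lr=self.initial_lr,
            min_lr=self.min_lr,
            lr_halving_patience=self.lr_halving_patience,
            validations_per_epoch=self.validations_per_epoch,
            max_epochs=self.max_epochs,
            seed=self.seed,
            crop_size=self.input_size,
        )
        model = EnhancerModel(self._model_config())
        self.model_, self.train_state_ = train(model, pairs, list(val_pairs), cfg, run_dir=run_dir)
        self.n_parameters_ = self.model_.n_parameters()
        return self

    @staticmethod
    def _center_crop(pair: BlockPair, size: int = EVAL_BLOCK) -> BlockPair:
        shape = pair.input_block.shape
        off = [(n - size) // 2 for n in shape]
        sl = tuple(slice(o, o + size) for o in off)
        return BlockPair(pair.input_block[sl], pair.target_block[sl], pair.position)

    def transform(self, X: Sequence[VoxelGrid]) -> list[VoxelGrid]:
        """Enhance full maps (resample → normalize → blocks → net → assemble)."""
        self._check_fitted()
        return [
            enhance_map(
                g, self.model_, batch_size=self.inference_batch_size, stride=self.stride
            ).map
            for g in X
        ]

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("MapEnhancer is not fitted; call fit() or load().")

    @classmethod
    def from_checkpoint(cls, path: str) -> "MapEnhancer":
        model, extra = load_checkpoint(path)
        cfg = model.config
        est = cls(
            input_size=cfg.input_size,
            channels=cfg.channels,
            num_heads=cfg.num_heads,
            epa_proj_dim=cfg.epa_proj_dim,
            transformer_layers_per_stage=cfg.transformer_layers_per_stage,
            dropout_p=cfg.dropout_p,
            seed=cfg.seed,
        )
        est.model_ = model
        est.n_parameters_ = model.n_parameters()
        return est
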