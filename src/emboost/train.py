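"""Training loop for the enhancement network.

Protocol: Adam from an initial learning rate of 5e-4; validation four
times per epoch; after four consecutive validations without improvement
of the best validation loss, the learning rate is halved, floored at
1e-5.  Training pairs (64³) are augmented on the fly — random 48³ crop,
random 90°-multiple rotation, random axis flips — while validation pairs
(48³) pass through unchanged.  The best-validation checkpoint is kept.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .blocks import BlockPair, EVAL_BLOCK, augment
from .model import EnhancerModel, masked_mse_loss, save_checkpoint
from .nn import Adam, no_grad

__all__ = ["TrainConfig", "TrainState", "plateau_step", "evaluate_pairs", "train"]

RESUME_FILE = "last_state.npz"


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 64
    initial_lr: float = 5e-4
    min_lr: float = 1e-5
    lr_halving_patience: int = 4
    validations_per_epoch: int = 4
    max_epochs: int = 10
    seed: int = 0
    improvement_vs_best: bool = True  # False: compare against previous value
    crop_size: int = EVAL_BLOCK

    def __post_init__(self):
        if self.min_lr > self.initial_lr:
            raise ValueError("min_lr must not exceed initial_lr")
        if self.lr_halving_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclasses.dataclass
class TrainState:
    epoch: int = 0
    step: int = 0
    current_lr: float = 5e-4
    min_lr: float = 1e-5
    patience: int = 4
    best_validation_loss: float = float("inf")
    last_validation_loss: float = float("inf")
    bad_validations: int = 0
    halvings_applied: int = 0
    train_losses: list = dataclasses.field(default_factory=list)
    val_losses: list = dataclasses.field(default_factory=list)
    improvement_vs_best: bool = True


def plateau_step(state: TrainState, new_val_loss: float) -> TrainState:
    """Apply one validation result to the plateau learning-rate rule.

    An improvement (strictly below the best loss seen so far, or below the
    previous value when ``improvement_vs_best`` is off) resets the
    non-improvement counter; ``patience`` consecutive non-improvements
    halve the learning rate (clamped at ``min_lr``) and reset the counter.
    Pure function of the validation-loss sequence: returns a new state.
    """
    s = dataclasses.replace(state, val_losses=list(state.val_losses))
    s.val_losses.append(float(new_val_loss))
    reference = s.best_validation_loss if s.improvement_vs_best else s.last_validation_loss
    improved = new_val_loss < reference
    s.last_validation_loss = float(new_val_loss)
    s.best_validation_loss = min(s.best_validation_loss, float(new_val_loss))
    if improved:
        s.bad_validations = 0
    else:
        s.bad_validations += 1
        if s.bad_validations >= s.patience:
            s.current_lr = max(s.current_lr / 2.0, s.min_lr)
            s.halvings_applied += 1
            s.bad_validations = 0
    return s


def evaluate_pairs(model: EnhancerModel, pairs: Sequence[BlockPair], batch_size: int = 8) -> float:
    """Mean masked MSE over pairs, without augmentation, in eval mode."""
    if not pairs:
        raise ValueError("validation set is empty")
    was_training = model.training
    model.eval()
    total, count = 0.0, 0
    try:
        with no_grad():
            for i in range(0, len(pairs), batch_size):
                chunk = pairs[i : i + batch_size]
                x = np.stack([p.input_block for p in chunk])[:, None]
                y = np.stack([p.target_block for p in chunk])[:, None]
                out = model.forward(x)
                loss = masked_mse_loss(out, y)
                total += float(loss.data) * len(chunk)
                count += len(chunk)
    finally:
        model.train(was_training)
    return total / count


def _save_resume_state(
    path: Path,
    model: EnhancerModel,
    opt: Adam,
    state: TrainState,
    rng: np.random.Generator,
    epoch_done: int,
) -> None:
    meta = {
        "epoch_done": epoch_done,
        "train_rng": rng.bit_generator.state,
        "dropout_rng": model.dropout_rng.bit_generator.state,
        "state": dataclasses.asdict(state),
        "adam_t": opt.t,
        "adam_lr": opt.lr,
    }
    arrays = {f"model:{k}": v for k, v in model.state_dict().items()}
    arrays.update({f"adam_m:{i}": m for i, m in enumerate(opt.m)})
    arrays.update({f"adam_v:{i}": v for i, v in enumerate(opt.v)})
    np.savez(
        str(path),
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **arrays,
    )


def _load_resume_state(
    path: Path, model: EnhancerModel, opt: Adam, rng: np.random.Generator
) -> tuple[TrainState, int]:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        model.load_state_dict(
            {k[len("model:"):]: z[k] for k in z.files if k.startswith("model:")}
        )
        for i in range(len(opt.m)):
            opt.m[i][...] = z[f"adam_m:{i}"]
            opt.v[i][...] = z[f"adam_v:{i}"]
    opt.t = int(meta["adam_t"])
    opt.lr = float(meta["adam_lr"])
    rng.bit_generator.state = meta["train_rng"]
    model.dropout_rng.bit_generator.state = meta["dropout_rng"]
    state = TrainState(**meta["state"])
    return state, int(meta["epoch_done"])


def train(
    model: EnhancerModel,
    train_pairs: Sequence[BlockPair],
    val_pairs: Sequence[BlockPair],
    cfg: TrainConfig,
    run_dir: str | Path | None = None,
    resume_from: str | Path | None = None,
) -> tuple[EnhancerModel, TrainState]:
    """Train ``model`` on 64³ train pairs against 48³ validation pairs.

    Per step: augment the batch, forward, masked MSE, Adam update.  The
    validation loss is evaluated ``validations_per_epoch`` times per epoch
    and drives the plateau halving rule.  All randomness derives from
    ``cfg.seed``.  When ``run_dir`` is given, a loss CSV log, the
    best-validation checkpoint and a per-epoch resume snapshot are written
    there; ``resume_from`` restores a snapshot (weights, optimizer moments,
    random-generator states, schedule state) so interrupted training
    continues exactly as if it had never stopped.
    """
    if not train_pairs:
        raise ValueError("training set is empty")
    if not val_pairs:
        raise ValueError("validation set is empty")

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    opt = Adam(model.parameters(), lr=cfg.initial_lr)
    state = TrainState(
        current_lr=cfg.initial_lr,
        min_lr=cfg.min_lr,
        patience=cfg.lr_halving_patience,
        improvement_vs_best=cfg.improvement_vs_best,
    )

    run_dir = Path(run_dir) if run_dir is not None else None
    log_rows: list[dict] = []
    best_ckpt = run_dir / "best.ckpt.npz" if run_dir else None
    if run_dir:
        run_dir.mkdir(parents=True, exist_ok=True)

    start_epoch = 0
    if resume_from is not None:
        state, epoch_done = _load_resume_state(Path(resume_from), model, opt, rng)
        start_epoch = epoch_done + 1

    n = len(train_pairs)
    steps_per_epoch = max(1, (n + cfg.batch_size - 1) // cfg.batch_size)
    # validate at the 1/v, 2/v, ..., v/v marks of each epoch
    val_marks = sorted(
        {max(1, round(steps_per_epoch * q / cfg.validations_per_epoch))
         for q in range(1, cfg.validations_per_epoch + 1)}
    )
    augmentable = any(d > cfg.crop_size for d in train_pairs[0].input_block.shape)

    model.train()
    for epoch in range(start_epoch, cfg.max_epochs):
        state.epoch = epoch
        order = rng.permutation(n)
        for bstart in range(0, n, cfg.batch_size):
            batch_idx = order[bstart : bstart + cfg.batch_size]
            xs, ys, positions = [], [], []
            for j in batch_idx:
                pair = train_pairs[j]
                if augmentable:
                    pair, _ = augment(pair, rng, crop_size=cfg.crop_size)
                xs.append(pair.input_block)
                ys.append(pair.target_block)
                positions.append(pair.position)
            x = np.stack(xs)[:, None]
            y = np.stack(ys)[:, None]
            out = model.forward(x)
            loss = masked_mse_loss(out, y)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, step {state.step}; "
                    f"block positions {positions}"
                )
            opt.zero_grad()
            loss.backward()
            opt.lr = state.current_lr
            opt.step()
            state.step += 1
            state.train_losses.append(float(loss.data))
            log_rows.append(
                {"epoch": epoch, "step": state.step, "kind": "train",
                 "loss": float(loss.data), "lr": state.current_lr}
            )

            step_in_epoch = (bstart // cfg.batch_size) + 1
            if step_in_epoch in val_marks:
                val_loss = evaluate_pairs(model, val_pairs, batch_size=cfg.batch_size)
                improved = val_loss < state.best_validation_loss
                state = plateau_step(state, val_loss)
                log_rows.append(
                    {"epoch": epoch, "step": state.step, "kind": "val",
                     "loss": val_loss, "lr": state.current_lr}
                )
                if improved and best_ckpt is not None:
                    save_checkpoint(
                        model, best_ckpt,
                        extra={"epoch": epoch, "step": state.step, "val_loss": val_loss,
                               "seed": cfg.seed},
                    )
        if run_dir:
            _save_resume_state(run_dir / RESUME_FILE, model, opt, state, rng, epoch)
    if run_dir:
        with open(run_dir / "losses.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "step", "kind", "loss", "lr"])
            writer.writeheader()
            writer.writerows(log_rows)
    return model, state
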