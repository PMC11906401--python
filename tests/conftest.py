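"""Shared fixtures.

The expensive fixture is ``e2e``: it generates the synthetic study
(8 training maps, 2 validation maps, 2 held-out test maps), trains the
tiny-configuration network for 10 epochs on one CPU and exposes the
trained model together with the do-nothing baseline.  It is session-scoped
so the end-to-end assertions share a single training run.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from emboost.blocks import BlockPair
from emboost.estimator import pairs_from_dataset
from emboost.fixtures import load_dataset, make_dataset
from emboost.grid import VoxelGrid
from emboost.model import EnhancerModel, ModelConfig, masked_mse
from emboost.train import TrainConfig, train

E2E_SEEDS = {"train": 100, "val": 200, "test": 300}


def tiny_config(**overrides) -> ModelConfig:
    """A fast 16³ four-stage configuration for unit tests."""
    kw = dict(input_size=16, channels=(4, 4, 8, 8), num_heads=2, epa_proj_dim=16, seed=3)
    kw.update(overrides)
    return ModelConfig(**kw)


def noise_pairs(n: int, size: int, seed: int = 42) -> list[BlockPair]:
    """Synthetic (noisy, clean) block pairs for quick training smoke tests."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        t = np.clip(rng.normal(0.15, 0.25, (size,) * 3), 0, 1).astype(np.float32)
        x = np.clip(t + rng.normal(0, 0.05, (size,) * 3), 0, 1).astype(np.float32)
        out.append(BlockPair(x, t, (0, 0, 0)))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_grid(rng):
    data = rng.random((20, 20, 20), dtype=np.float32)
    return VoxelGrid(data, voxel_size=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))


@dataclasses.dataclass
class E2EResult:
    model: EnhancerModel
    state: object
    baseline_mse: float
    enhanced_mse: float
    test_pairs: list
    test_manifest: dict


@pytest.fixture(scope="session")
def e2e(tmp_path_factory) -> E2EResult:
    """Train the tiny model on the fixed synthetic study conditions."""
    root = tmp_path_factory.mktemp("e2e")
    make_dataset(root / "train", 8, seed=E2E_SEEDS["train"])
    make_dataset(root / "val", 2, box=48.0, n_atoms=80, seed=E2E_SEEDS["val"])
    test_manifest = make_dataset(root / "test", 2, seed=E2E_SEEDS["test"])
    test_manifest["root"] = str(root / "test")

    train_pairs = pairs_from_dataset(load_dataset(root / "train"), mode="train")
    val_pairs = pairs_from_dataset(load_dataset(root / "val"), mode="eval")
    test_pairs = pairs_from_dataset(load_dataset(root / "test"), mode="eval")

    baseline = float(
        np.mean([masked_mse(p.input_block, p.target_block) for p in test_pairs])
    )
    model = EnhancerModel(
        ModelConfig(channels=(4, 8, 16, 32), num_heads=2, epa_proj_dim=32, seed=0)
    )
    model, state = train(
        model, train_pairs, val_pairs, TrainConfig(batch_size=1, max_epochs=10, seed=0)
    )
    from emboost.train import evaluate_pairs

    enhanced = evaluate_pairs(model, test_pairs)
    return E2EResult(model, state, baseline, enhanced, test_pairs, test_manifest)
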