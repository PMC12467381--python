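"""Shared fixtures: featurised synthetic worlds and trained models.

The expensive fixtures are session-scoped so the planted-motif benchmark is
generated and trained exactly once per test run.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from offtarget.featurization import morgan_fingerprint, protein_embed, train_kmer_embeddings
from offtarget.model import InteractionModel, ModelConfig
from offtarget.synthetic import generate_world
from offtarget.training import (
    InteractionDataset,
    TrainingConfig,
    contrastive_finetune,
    pretrain,
    train_validation_split,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@dataclasses.dataclass
class TrainedWorld:
    world: object
    compound_features: dict
    protein_features: dict
    model: InteractionModel
    model_init: InteractionModel
    train_pairs: object
    val_pairs: object
    pretrain_trace: list
    finetune_trace: list


def _featurize(world, seed):
    cf = {c.compound_id: morgan_fingerprint(c.smiles) for c in world.compounds}
    table = train_kmer_embeddings(
        [p.sequence for p in world.all_proteins], k=3, dimension=100, epochs=3,
        seed=seed,
    )
    pf = {p.protein_id: protein_embed(p.sequence, table) for p in world.all_proteins}
    return cf, pf


def _train_world(world, seed):
    cf, pf = _featurize(world, seed)
    train_pairs, val_pairs = train_validation_split(world.pairs, 0.15, seed=seed)
    model = InteractionModel(ModelConfig(p=64, seed=seed))
    model_init = InteractionModel(ModelConfig(p=64, seed=seed))
    cfg = TrainingConfig(seed=seed, epochs=30, finetune_epochs=10)
    dataset = InteractionDataset(train_pairs, cf, pf)
    model, pre_trace = pretrain(model, dataset, cfg)
    positives = dataset.positive_pairs
    pool = [c.compound_id for c in world.compounds]
    model, ft_trace = contrastive_finetune(
        model, positives, pool, cfg, cf, pf,
        target_pool=[p.protein_id for p in world.targets],
    )
    return TrainedWorld(world, cf, pf, model, model_init, train_pairs, val_pairs,
                        pre_trace, ft_trace)


@pytest.fixture(scope="session")
def default_world():
    """The default planted-motif benchmark world (200 compounds, 100 targets)."""
    return generate_world(seed=7)


@pytest.fixture(scope="session")
def trained(default_world):
    """Model pre-trained 30 epochs + fine-tuned 10 on the default world."""
    return _train_world(default_world, seed=7)


@pytest.fixture(scope="session")
def trained_null():
    """Same conditions on the null world (labels shuffled, rule severed)."""
    return _train_world(generate_world(seed=7, null_world=True), seed=7)


@pytest.fixture(scope="session")
def tiny_world():
    """A fast world for unit tests that only need structural validity."""
    return generate_world(n_compounds=24, n_targets=12, n_positive_per_target=3,
                          n_controls=12, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
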