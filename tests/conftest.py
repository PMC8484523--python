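"""Shared fixtures.

Heavy session fixtures (trained models) are defined here so that the
learning-curve, time-course and visual-world tests share the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from lexcompnet.evaluation import TrainingMonitor
from lexcompnet.grunet import GRUWordRecognizer
from lexcompnet.phonology import PhoneInventory, VocabularyItem
from lexcompnet.pipeline import assemble, build_dataset
from lexcompnet.synth import (
    SynthConfig,
    gen_phone_inventory,
    gen_semvis,
    gen_vocabulary,
    gen_vwp_fixture,
)

# the small study conditions for the multi-seed property suite: one fixed
# vocabulary (as in the reference design: one vocabulary, many model seeds)
SMALL_CONFIG = SynthConfig(
    seed=0,
    n_items=18,
    n_categories=4,
    n_slots=4,
    length_range=(2, 3),
    sem_dims=24,
    vis_raw_dims=48,
    vis_dims=14,
    n_popular_onsets=3,
    popular_onset_mass=0.75,
    sem_flip_prob=0.2,
    vis_flip_prob=0.1,
)
MODEL_SEEDS = [101, 202, 303, 404, 505]


@pytest.fixture(scope="session")
def toy_inventory() -> PhoneInventory:
    """Five-phone deterministic inventory for unit tests."""
    feats = np.zeros((5, 20))
    for i in range(5):
        feats[i, : i + 1] = 1.0  # distinct prefix codes, never all-ones
    return PhoneInventory(
        phones=["b", "k", "t", "a", "o"],
        features=feats,
        phone_class=["consonant", "consonant", "consonant", "vowel", "vowel"],
    )


@pytest.fixture(scope="session")
def vwp_fixture():
    return gen_vwp_fixture(0)


def train_model(ds, seed, epochs=20000, eval_every=250):
    monitor = TrainingMonitor(
        X=ds.X, offsets=ds.offsets, semvis_targets=ds.semvis_targets,
        lexical_targets=ds.lexical_targets, item_ids=ds.item_ids, spec=ds.spec,
    )
    model = GRUWordRecognizer(
        hidden_dim=ds.spec.total_dim, epochs=epochs, eval_every=eval_every,
        convergence_patience=2, random_state=seed,
    )
    model.fit(ds.X, ds.Y, eval_fn=monitor)
    return model, monitor


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SMALL_CONFIG
    inv = gen_phone_inventory(cfg)
    vocab = gen_vocabulary(cfg, inv)
    sem, vis = gen_semvis(cfg, vocab)
    ds, _ = build_dataset(vocab, inv, sem, vis, vis_k=cfg.vis_dims,
                          n_slots=cfg.n_slots)
    return ds


@pytest.fixture(scope="session")
def small_runs(small_dataset):
    """Five models (seeds) trained on the fixed small vocabulary."""
    return {
        seed: train_model(small_dataset, seed) for seed in MODEL_SEEDS
    }


@pytest.fixture(scope="session")
def fixture_dataset(vwp_fixture):
    return assemble(vwp_fixture.vocab, vwp_fixture.inventory,
                    vwp_fixture.sem_binary, vwp_fixture.vis_binary,
                    n_slots=vwp_fixture.n_slots)


@pytest.fixture(scope="session")
def fixture_runs(fixture_dataset):
    """Five models trained on the engineered visual-world vocabulary."""
    return {
        seed: train_model(fixture_dataset, seed) for seed in MODEL_SEEDS
    }
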