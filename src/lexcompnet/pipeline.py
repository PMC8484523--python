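"""Assemble model-ready tensors from a vocabulary and its representations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phonology import (
    PhoneInventory,
    VocabularyItem,
    build_lexical_vector,
    build_unfolding_matrix,
    cohort_of,
)
from .representations import (
    AggregateSpec,
    preprocess_semantic,
    preprocess_visual,
)


@dataclass
class Dataset:
    """Everything a training/evaluation run needs, in vocabulary order."""

    item_ids: list[str]
    vocab: list[VocabularyItem]
    inventory: PhoneInventory
    X: np.ndarray  # (n, T, n_features) padded unfolding matrices
    offsets: np.ndarray  # (n,) last non-padded timestep per item
    sem_binary: np.ndarray
    vis_binary: np.ndarray
    lexical: np.ndarray
    Y: np.ndarray  # (n, total_dim) aggregate targets
    spec: AggregateSpec
    n_slots: int

    @property
    def semvis_targets(self) -> np.ndarray:
        return self.Y[:, self.spec.semvis]

    @property
    def lexical_targets(self) -> np.ndarray:
        return self.Y[:, self.spec.lexical]

    def item_lengths(self) -> dict[str, int]:
        return {v.item_id: len(v) for v in self.vocab}

    def cohort_sizes(self) -> dict[str, int]:
        return {v.item_id: len(cohort_of(v, self.vocab)) for v in self.vocab}


def assemble(
    vocab: list[VocabularyItem],
    inv: PhoneInventory,
    sem_binary: np.ndarray,
    vis_binary: np.ndarray,
    n_slots: int = 10,
) -> Dataset:
    """Build padded unfolding inputs and aggregate targets from binary representations."""
    mats = [build_unfolding_matrix(v.label, inv, n_slots=n_slots, pad=True) for v in vocab]
    X = np.stack([m.values for m in mats])
    offsets = np.array([m.offset_row for m in mats])
    lex = np.vstack([build_lexical_vector(v.label, inv, n_slots=n_slots) for v in vocab])
    spec = AggregateSpec(sem_binary.shape[1], vis_binary.shape[1], lex.shape[1])
    Y = np.hstack([sem_binary, vis_binary, lex])
    return Dataset(
        item_ids=[v.item_id for v in vocab],
        vocab=list(vocab),
        inventory=inv,
        X=X,
        offsets=offsets,
        sem_binary=np.asarray(sem_binary, dtype=float),
        vis_binary=np.asarray(vis_binary, dtype=float),
        lexical=lex,
        Y=Y,
        spec=spec,
        n_slots=n_slots,
    )


def build_dataset(
    vocab: list[VocabularyItem],
    inv: PhoneInventory,
    sem_values: np.ndarray,
    vis_values: np.ndarray,
    vis_k: int = 150,
    z_cut: float = 2.0,
    n_slots: int = 10,
) -> tuple[Dataset, float]:
    """Full preprocessing path from raw real-valued matrices.

    Semantic: outlier replacement → median binarization.
    Visual: outlier replacement → PCA to ``vis_k`` dims → median binarization.
    Returns the dataset and the visual PCA cumulative variance explained.
    """
    sem_bin = preprocess_semantic(sem_values, z_cut)
    vis_bin, var = preprocess_visual(vis_values, vis_k, z_cut)
    return assemble(vocab, inv, sem_bin, vis_bin, n_slots=n_slots), var
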