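"""Semantic/visual representation preprocessing and Jaccard similarity.

Real-valued embedding matrices (one row per vocabulary item) are cleaned
by replacing per-dimension outliers with that dimension's median,
optionally reduced with PCA, and digitised into binary vectors by a
per-dimension median split.  Items are compared with the Jaccard index
of their binary vectors, and the three binary representations (semantic,
visual, lexical) are concatenated into one static aggregate target.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

SEM_DIM = 100
VIS_DIM = 150
LEX_DIM = 200


class OutlierReplacer(TransformerMixin, BaseEstimator):
    """Replace per-dimension outliers (|z| > z_cut) with the dimension median.

    Statistics (mean, sd, median) are computed once per dimension across
    items on the raw matrix; replacements are then applied in one pass,
    so the transform is idempotent on its own output.  Zero-variance
    dimensions are left untouched (their z-scores are treated as 0).
    """

    def __init__(self, z_cut: float = 2.0):
        self.z_cut = z_cut

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=3)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0)
        self.median_ = np.median(X, axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X).copy()
        nonconst = self.scale_ > 0
        z = np.zeros_like(X)
        z[:, nonconst] = (X[:, nonconst] - self.mean_[nonconst]) / self.scale_[nonconst]
        mask = np.abs(z) > self.z_cut
        X[mask] = np.broadcast_to(self.median_, X.shape)[mask]
        return X


class MedianBinarizer(TransformerMixin, BaseEstimator):
    """Digitise each dimension into two bins split at its median.

    Values strictly greater than the median map to 1, the rest
    (including median ties) to 0; ``ties_to_one`` flips the tie policy.
    """

    def __init__(self, ties_to_one: bool = False):
        self.ties_to_one = ties_to_one

    def fit(self, X, y=None):
        X = check_array(X)
        self.median_ = np.median(X, axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if self.ties_to_one:
            return (X >= self.median_).astype(float)
        return (X > self.median_).astype(float)


def replace_outliers(values: np.ndarray, z_cut: float = 2.0) -> np.ndarray:
    """Functional form of :class:`OutlierReplacer` (fit and transform on one matrix)."""
    return OutlierReplacer(z_cut=z_cut).fit_transform(values)


def reduce_dims(values: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Project onto the top-k principal components.

    Returns the reduced matrix and the cumulative fraction of variance
    explained by the k retained components.
    """
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    if not 1 <= k <= min(n - 1, d):
        raise ValueError(f"k={k} out of range for a {n}x{d} matrix")
    pca = PCA(n_components=k, svd_solver="full", random_state=0)
    reduced = pca.fit_transform(values)
    return reduced, float(pca.explained_variance_ratio_.sum())


def binarize_by_median(values: np.ndarray, ties_to_one: bool = False) -> np.ndarray:
    """Functional form of :class:`MedianBinarizer`."""
    return MedianBinarizer(ties_to_one=ties_to_one).fit_transform(values)


def jaccard(u: np.ndarray, v: np.ndarray) -> float:
    """Jaccard index of two binary vectors: |u∧v| / |u∨v|.

    Two all-zero vectors are identical, so the index is defined as 1.
    """
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    union = np.count_nonzero((u == 1) | (v == 1))
    if union == 0:
        return 1.0
    inter = np.count_nonzero((u == 1) & (v == 1))
    return inter / union


def jaccard_matrix(targets: np.ndarray, out: np.ndarray) -> np.ndarray:
    """Row-wise Jaccard of one binary vector ``out`` against each row of ``targets``."""
    out = np.asarray(out)
    targets = np.asarray(targets)
    inter = ((targets == 1) & (out == 1)).sum(axis=1)
    union = ((targets == 1) | (out == 1)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        j = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    return j


@dataclass(frozen=True)
class AggregateSpec:
    """Segment layout of the static aggregate target: semantic ‖ visual ‖ lexical."""

    sem_dim: int = SEM_DIM
    vis_dim: int = VIS_DIM
    lex_dim: int = LEX_DIM

    @property
    def total_dim(self) -> int:
        return self.sem_dim + self.vis_dim + self.lex_dim

    @property
    def semantic(self) -> slice:
        return slice(0, self.sem_dim)

    @property
    def visual(self) -> slice:
        return slice(self.sem_dim, self.sem_dim + self.vis_dim)

    @property
    def semvis(self) -> slice:
        return slice(0, self.sem_dim + self.vis_dim)

    @property
    def lexical(self) -> slice:
        return slice(self.sem_dim + self.vis_dim, self.total_dim)

    def segment(self, name: str) -> slice:
        return {
            "semantic": self.semantic,
            "visual": self.visual,
            "semvis": self.semvis,
            "lexical": self.lexical,
        }[name]


def aggregate_target(
    sem: np.ndarray,
    vis: np.ndarray,
    lex: np.ndarray,
    spec: AggregateSpec | None = None,
) -> np.ndarray:
    """Concatenate the binary semantic, visual and lexical vectors (fixed order)."""
    spec = spec or AggregateSpec(len(sem), len(vis), len(lex))
    for vec, want, name in (
        (sem, spec.sem_dim, "semantic"),
        (vis, spec.vis_dim, "visual"),
        (lex, spec.lex_dim, "lexical"),
    ):
        if len(vec) != want:
            raise ValueError(f"{name} vector has length {len(vec)}, expected {want}")
    return np.concatenate([sem, vis, lex])


def pairwise_jaccard_table(
    values: np.ndarray, item_ids: list[str] | None = None, kind: str = ""
) -> pd.DataFrame:
    """Jaccard index for every unordered item pair (self-pairs excluded)."""
    values = np.asarray(values)
    if not np.isin(values, (0, 1)).all():
        raise ValueError("pairwise Jaccard requires a binary matrix")
    n = values.shape[0]
    ids = item_ids if item_ids is not None else [str(i) for i in range(n)]
    rows = [
        (ids[a], ids[b], kind, jaccard(values[a], values[b]))
        for a, b in combinations(range(n), 2)
    ]
    return pd.DataFrame(rows, columns=["item_a", "item_b", "kind", "jaccard"])


def load_matrix(path) -> tuple[list[str], np.ndarray]:
    """Read a representation matrix (first column item_id, rest real values)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    ids = df.iloc[:, 0].tolist()
    return ids, df.iloc[:, 1:].to_numpy(dtype=float)


def save_matrix(path, item_ids: list[str], values: np.ndarray) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.DataFrame(values)
    df.insert(0, "item_id", item_ids)
    df.to_csv(path, sep=sep, index=False)


def preprocess_semantic(values: np.ndarray, z_cut: float = 2.0) -> np.ndarray:
    """Semantic pipeline: outlier replacement → median binarization."""
    return binarize_by_median(replace_outliers(values, z_cut))


def preprocess_visual(
    values: np.ndarray, k: int = VIS_DIM, z_cut: float = 2.0
) -> tuple[np.ndarray, float]:
    """Visual pipeline: outlier replacement → PCA to k dims → median binarization."""
    reduced, var = reduce_dims(replace_outliers(values, z_cut), k)
    return binarize_by_median(reduced), var
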