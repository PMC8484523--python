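"""Recognition scoring, learning-progress snapshots and activation time courses.

A vocabulary item's *activation* is the Jaccard index between the model
output (the hidden state, binarized at a threshold) and the item's static
binary representations.  Recognition is evaluated separately for the
semantic-visual segment and the lexical segment at *word offset* — the
last non-padded timestep of the item's unfolding input — and the item
with the highest activation is taken as the model's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grunet import GRUParams, batch_forward
from .representations import AggregateSpec, jaccard, jaccard_matrix

THRESHOLD = 0.5


def binarize_output(h: np.ndarray, threshold: float = THRESHOLD) -> np.ndarray:
    return (np.asarray(h) > threshold).astype(float)


def fuzzy_jaccard(u: np.ndarray, v: np.ndarray) -> float:
    """min/max generalisation of the Jaccard index for graded vectors."""
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    v = np.asarray(v, dtype=float)
    denom = np.maximum(u, v).sum()
    if denom == 0:
        return 1.0
    return float(np.minimum(u, v).sum() / denom)


def model_output_activation(
    h: np.ndarray,
    target_part: np.ndarray,
    segment: slice | str,
    spec: AggregateSpec | None = None,
    threshold: float = THRESHOLD,
    fuzzy: bool = False,
) -> float:
    """Activation of one candidate: slice h to the segment, binarize, Jaccard."""
    if isinstance(segment, str):
        if spec is None:
            raise ValueError("an AggregateSpec is required to resolve a named segment")
        segment = spec.segment(segment)
    part = np.asarray(h)[segment]
    if part.shape != np.asarray(target_part).shape:
        raise ValueError(
            f"segment of length {part.shape[0]} vs target of length {len(target_part)}"
        )
    if fuzzy:
        return fuzzy_jaccard(part, target_part)
    return jaccard(binarize_output(part, threshold), target_part)


@dataclass
class RecognitionResult:
    item_id: str
    best_semvis_item: str
    best_lexical_item: str
    semvis_correct: bool
    lexical_correct: bool
    semvis_activations: np.ndarray
    lexical_activations: np.ndarray
    semvis_tie: bool = False
    lexical_tie: bool = False


def _argmax_with_tie(act: np.ndarray) -> tuple[int, bool]:
    best = int(np.argmax(act))  # lowest index on ties
    tie = int(np.count_nonzero(act == act[best])) > 1
    return best, tie


def recognize(
    h: np.ndarray,
    semvis_targets: np.ndarray,
    lexical_targets: np.ndarray,
    item_ids: list[str],
    true_item: str,
    spec: AggregateSpec,
    threshold: float = THRESHOLD,
) -> RecognitionResult:
    """Score one model output against every vocabulary item's targets."""
    if len(item_ids) == 0:
        raise ValueError("vocabulary is empty")
    hb = binarize_output(h, threshold)
    sv_act = jaccard_matrix(semvis_targets, hb[spec.semvis])
    lx_act = jaccard_matrix(lexical_targets, hb[spec.lexical])
    sv_best, sv_tie = _argmax_with_tie(sv_act)
    lx_best, lx_tie = _argmax_with_tie(lx_act)
    return RecognitionResult(
        item_id=true_item,
        best_semvis_item=item_ids[sv_best],
        best_lexical_item=item_ids[lx_best],
        semvis_correct=item_ids[sv_best] == true_item,
        lexical_correct=item_ids[lx_best] == true_item,
        semvis_activations=sv_act,
        lexical_activations=lx_act,
        semvis_tie=sv_tie,
        lexical_tie=lx_tie,
    )


def offset_states(params: GRUParams, X: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Hidden state at each item's word offset (last non-padded timestep)."""
    hs, _ = batch_forward(params, np.asarray(X, dtype=float))
    return hs[np.arange(X.shape[0]), offsets, :]


def recognize_all(
    params: GRUParams,
    X: np.ndarray,
    offsets: np.ndarray,
    semvis_targets: np.ndarray,
    lexical_targets: np.ndarray,
    item_ids: list[str],
    spec: AggregateSpec,
    threshold: float = THRESHOLD,
) -> list[RecognitionResult]:
    h_off = offset_states(params, X, offsets)
    return [
        recognize(h_off[i], semvis_targets, lexical_targets, item_ids, item_ids[i],
                  spec, threshold)
        for i in range(len(item_ids))
    ]


def learning_snapshot(results: list[RecognitionResult]) -> dict[str, float]:
    """Fractions of items with both / either / neither constituent correct."""
    n = len(results)
    both = sum(r.semvis_correct and r.lexical_correct for r in results) / n
    sv_only = sum(r.semvis_correct and not r.lexical_correct for r in results) / n
    lx_only = sum(r.lexical_correct and not r.semvis_correct for r in results) / n
    neither = sum(not r.semvis_correct and not r.lexical_correct for r in results) / n
    return {
        "both": both,
        "semvis_only": sv_only,
        "lexical_only": lx_only,
        "neither": neither,
    }


@dataclass
class TrainingMonitor:
    """Evaluation callback for :meth:`GRUWordRecognizer.fit`.

    Records the four learning fractions and per-item correctness at every
    evaluation, and reports convergence when both constituents are
    recognized for 100% of items.
    """

    X: np.ndarray
    offsets: np.ndarray
    semvis_targets: np.ndarray
    lexical_targets: np.ndarray
    item_ids: list[str]
    spec: AggregateSpec
    threshold: float = THRESHOLD
    per_item: list = field(default_factory=list)  # (epoch, semvis_ok, lexical_ok)

    def __call__(self, params: GRUParams, epoch: int) -> dict:
        results = recognize_all(
            params, self.X, self.offsets, self.semvis_targets,
            self.lexical_targets, self.item_ids, self.spec, self.threshold,
        )
        snap = learning_snapshot(results)
        self.per_item.append(
            (
                epoch,
                np.array([r.semvis_correct for r in results]),
                np.array([r.lexical_correct for r in results]),
            )
        )
        return {
            "pct_both": 100.0 * snap["both"],
            "pct_semvis_only": 100.0 * snap["semvis_only"],
            "pct_lex_only": 100.0 * snap["lexical_only"],
            "pct_neither": 100.0 * snap["neither"],
            "converged": snap["both"] == 1.0,
        }

    def per_item_frame(self) -> pd.DataFrame:
        rows = []
        for epoch, sv, lx in self.per_item:
            for i, item in enumerate(self.item_ids):
                rows.append((epoch, item, bool(sv[i]), bool(lx[i])))
        return pd.DataFrame(rows, columns=["epoch", "item_id", "semvis_correct",
                                           "lexical_correct"])


def epochs_to_lexical_criterion(per_item: pd.DataFrame) -> pd.Series:
    """First evaluated epoch at which each item's lexical output is correct
    and stays correct through the end of training (NaN if never)."""
    out = {}
    for item, grp in per_item.groupby("item_id", sort=False):
        grp = grp.sort_values("epoch")
        ok = grp["lexical_correct"].to_numpy()
        sustained = np.logical_and.accumulate(ok[::-1])[::-1]
        idx = np.nonzero(sustained)[0]
        out[item] = grp["epoch"].iloc[idx[0]] if idx.size else np.nan
    return pd.Series(out, name="criterion_epoch")


def split_learning_curves(
    per_item: pd.DataFrame,
    item_lengths: dict[str, int],
    cohort_sizes: dict[str, int],
    length_cut: int = 5,
    cohort_cut: int = 15,
) -> pd.DataFrame:
    """Lexical learning curves grouped by label length and cohort size.

    Long labels have ``length_cut`` phones or more; large cohorts contain
    ``cohort_cut`` items or more.  Empty groups are reported with NaN.
    """
    df = per_item.copy()
    df["length_group"] = df["item_id"].map(
        lambda i: "long" if item_lengths[i] >= length_cut else "short"
    )
    df["cohort_group"] = df["item_id"].map(
        lambda i: "large" if cohort_sizes[i] >= cohort_cut else "small"
    )
    frames = []
    for kind in ("length_group", "cohort_group"):
        g = (
            df.groupby(["epoch", kind])["lexical_correct"].mean().rename("pct_correct")
            * 100.0
        ).reset_index()
        g = g.rename(columns={kind: "group"})
        g["split"] = kind.replace("_group", "")
        frames.append(g)
    return pd.concat(frames, ignore_index=True)


def activation_timecourse(
    params: GRUParams,
    unfolding: np.ndarray,
    aggregate: np.ndarray,
    spec: AggregateSpec,
    threshold: float = THRESHOLD,
) -> pd.DataFrame:
    """Per-timestep semantic-visual and lexical self-activation for one item."""
    hs, _ = batch_forward(params, np.asarray(unfolding, dtype=float)[None])
    hs = hs[0]
    sv_t = aggregate[spec.semvis]
    lx_t = aggregate[spec.lexical]
    rows = [
        (
            t,
            jaccard(binarize_output(h[spec.semvis], threshold), sv_t),
            jaccard(binarize_output(h[spec.lexical], threshold), lx_t),
        )
        for t, h in enumerate(hs)
    ]
    return pd.DataFrame(rows, columns=["timestep", "semvis_activation",
                                       "lexical_activation"])
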