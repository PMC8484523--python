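"""Target-absent visual-world trial construction and simulation.

A trial presents the model with the unfolding label of a *target* that is
absent from the display, alongside four candidate referents: a
phonological competitor (PREL, shares the onset phone), a semantic
competitor (SREL), a visual competitor (VREL) and an unrelated item
(UREL).  Semantic/visual (un)relatedness is decided by where the pair's
Jaccard index falls among all pairwise comparisons across the vocabulary:
related means at or above the 85th percentile, unrelated at or below the
15th.  At each timestep the model's semantic-visual output segment is
compared (Jaccard) with each candidate's static semantic-visual
representation; the activation stands in for attention — there is no
separate attention mechanism.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import THRESHOLD, binarize_output
from .grunet import GRUParams, batch_forward
from .phonology import PhoneInventory, VocabularyItem
from .representations import AggregateSpec, jaccard_matrix

CANDIDATE_CLASSES = ("PREL", "SREL", "VREL", "UREL")


@dataclass(frozen=True)
class TrialSpec:
    target_id: str
    prel_id: str
    srel_id: str
    vrel_id: str
    urel_id: str

    def candidate_ids(self) -> tuple[str, str, str, str]:
        return (self.prel_id, self.srel_id, self.vrel_id, self.urel_id)


@dataclass
class TrialResult:
    spec: TrialSpec
    activations: np.ndarray  # (T, 4) raw, columns in CANDIDATE_CLASSES order
    relative: np.ndarray  # (T, 4) candidate minus UREL
    attended: np.ndarray  # (T,) index into CANDIDATE_CLASSES


def rhyme_of(label: tuple[str, ...], inv: PhoneInventory, mode: str = "last-vowel",
             n_final: int = 2) -> tuple[str, ...]:
    """The rhyme portion of a label: from its last vowel to the end
    (``last-vowel``, default) or its final ``n_final`` phones (``final-n``)."""
    if mode == "final-n":
        return tuple(label[-n_final:])
    if mode != "last-vowel":
        raise ValueError(f"unknown rhyme mode {mode!r}")
    vowels = set(inv.vowels())
    for i in range(len(label) - 1, -1, -1):
        if label[i] in vowels:
            return tuple(label[i:])
    return tuple(label)  # no vowel: whole label


@dataclass
class RelatednessTables:
    """Pairwise Jaccard matrices plus the vocabulary-wide percentile cutoffs."""

    item_ids: list[str]
    sem: np.ndarray  # (n, n) symmetric, diagonal unused
    vis: np.ndarray
    sem_hi: float
    sem_lo: float
    vis_hi: float
    vis_lo: float

    @classmethod
    def from_binary(
        cls,
        item_ids: list[str],
        sem_binary: np.ndarray,
        vis_binary: np.ndarray,
        pct_hi: float = 85.0,
        pct_lo: float = 15.0,
    ) -> "RelatednessTables":
        def pairwise(mat):
            n = mat.shape[0]
            out = np.zeros((n, n))
            for i in range(n):
                out[i] = jaccard_matrix(mat, mat[i])
            return out

        sem = pairwise(np.asarray(sem_binary))
        vis = pairwise(np.asarray(vis_binary))
        iu = np.triu_indices(len(item_ids), k=1)  # self-pairs excluded
        return cls(
            item_ids=list(item_ids),
            sem=sem,
            vis=vis,
            sem_hi=float(np.percentile(sem[iu], pct_hi)),
            sem_lo=float(np.percentile(sem[iu], pct_lo)),
            vis_hi=float(np.percentile(vis[iu], pct_hi)),
            vis_lo=float(np.percentile(vis[iu], pct_lo)),
        )

    def index_of(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"unknown item {item_id!r}") from None


def relatedness_flags(
    a: VocabularyItem,
    b: VocabularyItem,
    tables: RelatednessTables,
    inv: PhoneInventory,
    rhyme_mode: str = "last-vowel",
) -> dict[str, bool]:
    """Pairwise relatedness of two distinct items (ties at a cutoff count as satisfying)."""
    if a.item_id == b.item_id:
        raise ValueError("self-comparison is not defined")
    ia, ib = tables.index_of(a.item_id), tables.index_of(b.item_id)
    sem_j = tables.sem[ia, ib]
    vis_j = tables.vis[ia, ib]
    return {
        "onset_share": a.onset == b.onset,
        "rhyme_share": rhyme_of(a.label, inv, rhyme_mode) == rhyme_of(b.label, inv, rhyme_mode),
        "sem_related": sem_j >= tables.sem_hi,
        "sem_unrelated": sem_j <= tables.sem_lo,
        "vis_related": vis_j >= tables.vis_hi,
        "vis_unrelated": vis_j <= tables.vis_lo,
    }


def select_trials(
    vocab: list[VocabularyItem],
    tables: RelatednessTables,
    inv: PhoneInventory,
    rhyme_mode: str = "last-vowel",
) -> list[TrialSpec]:
    """Exhaustively enumerate all valid (target, PREL, SREL, VREL, UREL) tuples.

    Targets are restricted to consonant-onset items.  An empty result is
    permitted (e.g., no shared onsets in the vocabulary).
    """
    consonants = set(inv.consonants())
    by_id = {v.item_id: v for v in vocab}
    order = sorted(by_id)  # row-order invariance
    trials: list[TrialSpec] = []
    for tid in order:
        target = by_id[tid]
        if target.onset not in consonants:
            continue
        prels, srels, vrels, urels = [], [], [], []
        for cid in order:
            if cid == tid:
                continue
            f = relatedness_flags(target, by_id[cid], tables, inv, rhyme_mode)
            phon_unrelated = not f["onset_share"] and not f["rhyme_share"]
            if (f["onset_share"] and not f["rhyme_share"]
                    and f["sem_unrelated"] and f["vis_unrelated"]):
                prels.append(cid)
            if f["sem_related"] and f["vis_unrelated"] and phon_unrelated:
                srels.append(cid)
            if f["vis_related"] and f["sem_unrelated"] and phon_unrelated:
                vrels.append(cid)
            if f["sem_unrelated"] and f["vis_unrelated"] and phon_unrelated:
                urels.append(cid)
        for p, s, v, u in itertools.product(prels, srels, vrels, urels):
            if len({tid, p, s, v, u}) == 5:
                trials.append(TrialSpec(tid, p, s, v, u))
    return trials


def run_trial(
    params: GRUParams,
    spec: TrialSpec,
    target_unfolding: np.ndarray,
    semvis_targets: dict[str, np.ndarray],
    agg: AggregateSpec,
    threshold: float = THRESHOLD,
) -> TrialResult:
    """Simulate one target-absent trial over the unfolding of the target label."""
    hs, _ = batch_forward(params, np.asarray(target_unfolding, dtype=float)[None])
    hs = hs[0]
    cand = np.vstack([semvis_targets[c] for c in spec.candidate_ids()])
    if cand.shape[1] != agg.semvis.stop:
        raise ValueError("candidate semantic-visual vectors do not match the segment size")
    T = hs.shape[0]
    acts = np.empty((T, 4))
    for t in range(T):
        out = binarize_output(hs[t, agg.semvis], threshold)
        acts[t] = jaccard_matrix(cand, out)
    relative = acts - acts[:, [3]]  # subtract UREL
    attended = np.argmax(acts, axis=1)  # lowest index wins ties
    return TrialResult(spec=spec, activations=acts, relative=relative, attended=attended)


def results_frame(results: list[TrialResult], model_seed: int | None = None) -> pd.DataFrame:
    """Long-format table: trial, timestep, class, activation, relative, attended."""
    rows = []
    for k, res in enumerate(results):
        for t in range(res.activations.shape[0]):
            for j, cls in enumerate(CANDIDATE_CLASSES):
                rows.append(
                    (model_seed, k, res.spec.target_id, t, cls,
                     res.activations[t, j], res.relative[t, j],
                     CANDIDATE_CLASSES[res.attended[t]])
                )
    return pd.DataFrame(
        rows,
        columns=["model_seed", "trial", "target", "timestep", "class",
                 "activation", "relative_activation", "attended"],
    )


def grand_average(
    frames: list[pd.DataFrame],
    n_boot: int = 500,
    ci: float = 95.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, int | None]:
    """Mean relative activation per timestep per candidate class, pooled over
    trials and model seeds, with bootstrap percentile CIs.

    Also returns the crossover timestep: the first timestep at which the
    mean SREL relative activation exceeds the mean PREL relative
    activation after PREL has led (None if there is no crossover).
    """
    if not frames:
        raise ValueError("no trial results to average")
    df = pd.concat(frames, ignore_index=True)
    rng = np.random.default_rng(seed)
    rows = []
    for (t, cls), grp in df.groupby(["timestep", "class"], sort=True):
        vals = grp["relative_activation"].to_numpy()
        mean = vals.mean()
        if len(vals) > 1:
            idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
            boots = vals[idx].mean(axis=1)
            lo, hi = np.percentile(boots, [(100 - ci) / 2, 100 - (100 - ci) / 2])
        else:
            lo = hi = mean
        rows.append((t, cls, mean, lo, hi, len(vals)))
    table = pd.DataFrame(
        rows, columns=["timestep", "class", "mean", "ci_lo", "ci_hi", "n"]
    )
    wide = table.pivot(index="timestep", columns="class", values="mean").sort_index()
    crossover = None
    led = False
    for t, row in wide.iterrows():
        if row["PREL"] > row["SREL"]:
            led = True
        elif led and row["SREL"] > row["PREL"]:
            crossover = int(t)
            break
    return table, crossover
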