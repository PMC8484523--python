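"""Synthetic vocabularies, phone inventories and semantic/visual matrices.

The generators emulate the statistical structure the model exploits —
category-clustered semantic vectors, visual vectors partially coupled to
the semantic categories, onset-phone frequencies that produce a few large
cohorts, and word lengths spanning a configurable range — so the whole
pipeline (preprocessing, training, evaluation, visual-world simulation)
can be exercised end to end without any external corpora.  Everything is
seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phonology import (
    SEG_SYMBOL,
    PhoneInventory,
    VocabularyItem,
)
from .vwp import RelatednessTables, TrialSpec, select_trials


@dataclass
class SynthConfig:
    """Study conditions for the synthetic dataset (defaults are the
    scaled-down conditions used throughout the test suite)."""

    n_items: int = 50
    n_categories: int = 6
    length_range: tuple[int, int] = (2, 4)
    n_slots: int = 5
    n_consonants: int = 14
    n_vowels: int = 6
    n_features: int = 20
    vowel_onset_frac: float = 0.06
    # fraction of onset probability mass concentrated on a few popular onsets
    n_popular_onsets: int = 4
    popular_onset_mass: float = 0.75
    sem_dims: int = 30
    vis_raw_dims: int = 60
    vis_dims: int = 20
    sem_flip_prob: float = 0.15
    vis_flip_prob: float = 0.08
    sem_vis_coupling: float = 0.3
    noise_sd: float = 0.2
    outlier_frac: float = 0.01
    outlier_scale: float = 4.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if not 1 <= lo <= hi <= self.n_slots - 1:
            raise ValueError("length_range must fit within the slot capacity")
        for name in ("vowel_onset_frac", "sem_flip_prob", "vis_flip_prob",
                     "sem_vis_coupling", "outlier_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")


def gen_phone_inventory(cfg: SynthConfig) -> PhoneInventory:
    """Random distinct binary feature codes; never the all-ones (segmentation)
    or all-zeros (silence) pattern."""
    n_phones = cfg.n_consonants + cfg.n_vowels
    if n_phones < 4:
        raise ValueError("need at least 4 phones")
    if 2**cfg.n_features <= n_phones:
        raise ValueError("feature space too small for distinct codes")
    rng = np.random.default_rng(cfg.seed)
    codes: list[tuple] = []
    seen = {tuple([1] * cfg.n_features), tuple([0] * cfg.n_features)}
    attempts = 0
    while len(codes) < n_phones:
        attempts += 1
        if attempts > 1000 * n_phones:
            raise RuntimeError("could not generate distinct phone codes")
        code = tuple(rng.integers(0, 2, cfg.n_features))
        if code not in seen:
            seen.add(code)
            codes.append(code)
    phones = [f"c{i}" for i in range(cfg.n_consonants)] + [
        f"v{i}" for i in range(cfg.n_vowels)
    ]
    classes = ["consonant"] * cfg.n_consonants + ["vowel"] * cfg.n_vowels
    return PhoneInventory(
        phones=phones,
        features=np.array(codes, dtype=float),
        phone_class=classes,
        seg_symbol=SEG_SYMBOL,
        n_features=cfg.n_features,
    )


def onset_weights(cfg: SynthConfig, inv: PhoneInventory) -> dict[str, float]:
    """Consonant-onset profile: a few popular onsets carry most of the mass,
    producing the large cohorts seen in toddler vocabularies."""
    cons = inv.consonants()
    k = min(cfg.n_popular_onsets, len(cons))
    w = {}
    for i, c in enumerate(cons):
        if i < k:
            w[c] = cfg.popular_onset_mass / k
        else:
            w[c] = (1.0 - cfg.popular_onset_mass) / max(len(cons) - k, 1)
    return w


def gen_labels(cfg: SynthConfig, inv: PhoneInventory) -> list[tuple[str, ...]]:
    """Distinct phone-sequence labels with configured lengths and onset profile."""
    rng = np.random.default_rng(cfg.seed + 1)
    cons = inv.consonants()
    vows = inv.vowels()
    w = onset_weights(cfg, inv)
    cons_p = np.array([w[c] for c in cons])
    cons_p /= cons_p.sum()
    labels: list[tuple[str, ...]] = []
    seen = set()
    attempts = 0
    lo, hi = cfg.length_range
    while len(labels) < cfg.n_items:
        attempts += 1
        if attempts > 2000 * cfg.n_items:
            raise RuntimeError("could not generate enough distinct labels")
        length = int(rng.integers(lo, hi + 1))
        if rng.random() < cfg.vowel_onset_frac:
            onset = vows[rng.integers(len(vows))]
        else:
            onset = cons[rng.choice(len(cons), p=cons_p)]
        # alternate consonant/vowel-ish tail for pronounceable-looking labels
        tail = []
        for j in range(length - 1):
            pool = vows if j % 2 == 0 else cons
            tail.append(pool[rng.integers(len(pool))])
        label = (onset, *tail)
        if label not in seen:
            seen.add(label)
            labels.append(label)
    return labels


def gen_vocabulary(cfg: SynthConfig, inv: PhoneInventory) -> list[VocabularyItem]:
    labels = gen_labels(cfg, inv)
    return [
        VocabularyItem(f"item{i:03d}", lab, f"cat{i % cfg.n_categories}")
        for i, lab in enumerate(labels)
    ]


def _continuousize(bits: np.ndarray, rng: np.random.Generator,
                   noise_sd: float, outlier_frac: float, outlier_scale: float) -> np.ndarray:
    vals = bits + rng.normal(0.0, noise_sd, bits.shape)
    out_mask = rng.random(bits.shape) < outlier_frac
    signs = rng.choice([-1.0, 1.0], size=bits.shape)
    vals = np.where(out_mask, bits + signs * outlier_scale, vals)
    return vals


def gen_semvis_bits(
    cfg: SynthConfig, vocab: list[VocabularyItem]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Underlying binary semantic/visual vectors plus visual-cluster labels.

    Semantic vectors are category prototypes with per-dimension flip noise.
    Visual vectors mix a category-linked prototype (a ``sem_vis_coupling``
    fraction of dimensions) with an independent visual-cluster prototype,
    so semantic and visual relatedness are correlated but dissociable.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    cats = sorted({v.category for v in vocab})
    cat_idx = np.array([cats.index(v.category) for v in vocab])
    n = len(vocab)

    def hierarchical_protos(n_protos: int, dims: int) -> np.ndarray:
        # prototypes are mutations of a shared base at per-prototype rates,
        # so between-prototype similarity is graded rather than uniform and
        # the extreme percentile tails are stably populated
        base = rng.integers(0, 2, dims).astype(float)
        rates = rng.uniform(0.15, 0.5, n_protos)
        protos = np.tile(base, (n_protos, 1))
        flip = rng.random(protos.shape) < rates[:, None]
        return np.where(flip, 1.0 - protos, protos)

    sem_protos = hierarchical_protos(len(cats), cfg.sem_dims)
    sem_bits = sem_protos[cat_idx]
    flips = rng.random(sem_bits.shape) < cfg.sem_flip_prob
    sem_bits = np.where(flips, 1.0 - sem_bits, sem_bits)

    # visual clusters independent of semantic category; a sem_vis_coupling
    # fraction of visual dimensions is driven by the item's category instead
    vis_cluster = rng.integers(0, len(cats), n)
    vis_cat_protos = hierarchical_protos(len(cats), cfg.vis_raw_dims)
    vis_clu_protos = hierarchical_protos(len(cats), cfg.vis_raw_dims)
    coupled_dims = rng.random(cfg.vis_raw_dims) < cfg.sem_vis_coupling
    vis_bits = np.where(coupled_dims, vis_cat_protos[cat_idx], vis_clu_protos[vis_cluster])
    flips = rng.random(vis_bits.shape) < cfg.vis_flip_prob
    vis_bits = np.where(flips, 1.0 - vis_bits, vis_bits)
    return sem_bits, vis_bits, vis_cluster


def gen_semvis(
    cfg: SynthConfig, vocab: list[VocabularyItem]
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous semantic (n, sem_dims) and visual (n, vis_raw_dims) matrices.

    The binary vectors of :func:`gen_semvis_bits` are continuousized with
    Gaussian noise plus sparse large-magnitude outliers so the
    preprocessing pipeline (outlier replacement → reduction → median
    binarization) is exercised end to end.
    """
    sem_bits, vis_bits, _ = gen_semvis_bits(cfg, vocab)
    rng = np.random.default_rng(cfg.seed + 3)
    sem = _continuousize(sem_bits, rng, cfg.noise_sd, cfg.outlier_frac, cfg.outlier_scale)
    vis = _continuousize(vis_bits, rng, cfg.noise_sd, cfg.outlier_frac, cfg.outlier_scale)
    return sem, vis


@dataclass
class VwpFixture:
    """A small hand-placed vocabulary guaranteed to contain one valid trial.

    Synthetic stand-in for a real vocabulary: semantic/visual vectors are
    engineered binary supports placing exactly one
    (target, PREL, SREL, VREL, UREL) tuple at the percentile extremes.
    """

    vocab: list[VocabularyItem]
    inventory: PhoneInventory
    sem_binary: np.ndarray
    vis_binary: np.ndarray
    n_slots: int
    expected_trials: tuple[TrialSpec, ...]

    def tables(self, pct_hi: float = 85.0, pct_lo: float = 15.0) -> RelatednessTables:
        return RelatednessTables.from_binary(
            [v.item_id for v in self.vocab], self.sem_binary, self.vis_binary,
            pct_hi, pct_lo,
        )


def _fixture_inventory() -> PhoneInventory:
    phones = ["b", "k", "t", "m", "s", "n", "f", "g", "p", "d",
              "a", "i", "o", "u", "e"]
    classes = ["consonant"] * 10 + ["vowel"] * 5
    # deterministic distinct codes: binary expansion of 1..15 over 20 features
    feats = np.zeros((len(phones), 20))
    for i in range(len(phones)):
        bits = np.array(list(np.binary_repr(i + 1, width=20)), dtype=float)
        feats[i] = bits
    return PhoneInventory(phones=phones, features=feats, phone_class=classes)


def _support(dims: list[int], size: int) -> np.ndarray:
    v = np.zeros(size)
    v[dims] = 1.0
    return v


def gen_vwp_fixture(seed: int = 0) -> VwpFixture:
    """Build and *verify* an 11-item vocabulary whose valid trials are known.

    The target ``t`` has two onset-sharing, rhyme-differing phonological
    competitors (``prel``/``prel2``) with extreme-low semantic/visual
    similarity to the target; an SREL/VREL at the extreme high end of one
    table and the low end of the other; a fully unrelated UREL; and five
    mid-similarity fillers that keep the percentile cutoffs away from the
    engineered pairs.  The two phonological competitors share most of
    their support, so the cohort blend the model outputs early in the
    trial crosses the binarization threshold on their shared dimensions —
    a miniature of the dense overlapping structure of corpus-derived
    vectors, without which a two-word cohort of disjoint supports sits
    exactly at threshold and no early phonological preference can show.
    Construction is verified by re-running the selection criteria; failure
    raises rather than silently returning.  ``seed`` permutes item order
    only (the selection must be order-invariant).
    """
    inv = _fixture_inventory()
    dim = 52
    labels = {
        "t": ("b", "a", "t"),
        "prel": ("b", "i", "k"),
        "prel2": ("b", "u", "s"),
        "srel": ("m", "o", "s"),
        "vrel": ("n", "u", "f"),
        "urel": ("g", "e", "p"),
        "f0": ("d", "a", "k"),
        "f1": ("k", "i", "m"),
        "f2": ("p", "o", "n"),
        "f3": ("s", "u", "d"),
        "f4": ("f", "e", "m"),
    }
    sem = {
        "t": list(range(10)),
        "srel": list(range(9)) + [10],
        "prel": list(range(11, 20)),
        "prel2": list(range(11, 18)) + [48, 49],  # shares 7 dims with prel
        "vrel": list(range(20, 29)),
        "urel": list(range(29, 38)),
    }
    vis = {
        "t": list(range(10)),
        "vrel": list(range(9)) + [10],
        "srel": list(range(11, 20)),
        "prel": list(range(20, 29)),
        "prel2": list(range(20, 27)) + [50, 51],
        "urel": list(range(29, 38)),
    }
    for i in range(5):
        # fillers overlap the target on two dimensions -> mid-range similarity
        sem[f"f{i}"] = [2 * i, 2 * i + 1] + list(range(38 + 2 * i, 40 + 2 * i))
        vis[f"f{i}"] = [2 * i, 2 * i + 1] + list(range(38 + 2 * i, 40 + 2 * i))
    order = list(labels)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    vocab = [VocabularyItem(name, labels[name], "cat0") for name in order]
    sem_mat = np.vstack([_support(sem[name], dim) for name in order])
    vis_mat = np.vstack([_support(vis[name], dim) for name in order])
    fixture = VwpFixture(
        vocab=vocab,
        inventory=inv,
        sem_binary=sem_mat,
        vis_binary=vis_mat,
        n_slots=4,
        expected_trials=(
            TrialSpec("t", "prel", "srel", "vrel", "urel"),
            TrialSpec("t", "prel2", "srel", "vrel", "urel"),
        ),
    )
    trials = select_trials(vocab, fixture.tables(), inv)
    if not set(fixture.expected_trials) <= set(trials):
        raise RuntimeError("fixture construction failed verification")
    return fixture
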