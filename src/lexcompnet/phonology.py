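"""Phonological encodings: dynamic unfolding matrices and static slotted lexical vectors.

Each phone is a binary vector of articulatory/phonological features
(20 by default).  A word's *dynamic* representation unfolds the phone
codes row by row over time, with two interpolated co-articulation rows
between consecutive phones (a feature moving 1→0 passes through 0.95
then 0.05).  A reserved segmentation character whose features are all 1
marks word offset.  The *static* lexical representation concatenates the
phone codes into fixed slots (10 by default, 200 features total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_FEATURES = 20
N_SLOTS = 10
SEG_SYMBOL = "#"


class UnknownPhoneError(KeyError):
    """A label contains a symbol absent from the phone inventory."""


class LabelCapacityError(ValueError):
    """A label is too long for the configured number of phone slots."""


@dataclass
class PhoneInventory:
    """Phone → binary feature-code table plus consonant/vowel class.

    The segmentation character (``seg_symbol``) is implicit: its code is
    all ones and it never appears among ``phones``.
    """

    phones: list[str]
    features: np.ndarray  # (n_phones, n_features) binary
    phone_class: list[str]  # "consonant" | "vowel", parallel to phones
    seg_symbol: str = SEG_SYMBOL
    n_features: int = N_FEATURES
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (len(self.phones), self.n_features):
            raise ValueError(
                f"feature table shape {self.features.shape} does not match "
                f"{len(self.phones)} phones x {self.n_features} features"
            )
        if not np.isin(self.features, (0.0, 1.0)).all():
            raise ValueError("phone feature codes must be binary")
        if self.seg_symbol in self.phones:
            raise ValueError("segmentation character may not appear as a phone")
        codes = {tuple(row) for row in self.features.astype(int)}
        if len(codes) != len(self.phones):
            raise ValueError("phone codes must be pairwise distinct")
        if tuple([1] * self.n_features) in codes:
            raise ValueError("no ordinary phone may use the all-ones segmentation code")
        if len(self.phone_class) != len(self.phones):
            raise ValueError("phone_class must parallel phones")
        self._index = {p: i for i, p in enumerate(self.phones)}

    @property
    def seg_code(self) -> np.ndarray:
        return np.ones(self.n_features)

    def __contains__(self, phone: str) -> bool:
        return phone in self._index or phone == self.seg_symbol

    def consonants(self) -> list[str]:
        return [p for p, c in zip(self.phones, self.phone_class) if c == "consonant"]

    def vowels(self) -> list[str]:
        return [p for p, c in zip(self.phones, self.phone_class) if c == "vowel"]

    @classmethod
    def from_csv(cls, path) -> "PhoneInventory":
        """Load a ``phone,class,f1..fN`` table; a segmentation row is optional."""
        df = pd.read_csv(path, dtype={"phone": str, "class": str})
        feat_cols = [c for c in df.columns if c.startswith("f")]
        seg_mask = df["class"].eq("segmentation")
        df = df[~seg_mask]
        return cls(
            phones=df["phone"].tolist(),
            features=df[feat_cols].to_numpy(),
            phone_class=df["class"].tolist(),
            n_features=len(feat_cols),
        )

    def to_csv(self, path) -> None:
        cols = {"phone": self.phones, "class": self.phone_class}
        for j in range(self.n_features):
            cols[f"f{j + 1}"] = self.features[:, j].astype(int)
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass
class VocabularyItem:
    item_id: str
    label: tuple[str, ...]  # phone symbols, segmentation character excluded
    category: str

    @property
    def onset(self) -> str:
        return self.label[0]

    def __len__(self) -> int:
        return len(self.label)


def load_vocabulary(path) -> list[VocabularyItem]:
    """Read an ``item_id,label,category`` CSV; labels are space-separated phones."""
    df = pd.read_csv(path, dtype=str)
    return [
        VocabularyItem(r.item_id, tuple(r.label.split()), r.category)
        for r in df.itertuples()
    ]


def save_vocabulary(items: Sequence[VocabularyItem], path) -> None:
    pd.DataFrame(
        {
            "item_id": [it.item_id for it in items],
            "label": [" ".join(it.label) for it in items],
            "category": [it.category for it in items],
        }
    ).to_csv(path, index=False)


@dataclass
class UnfoldingMatrix:
    """Timesteps × n_features matrix of a word's dynamic phonological input."""

    values: np.ndarray
    n_label_phones: int
    n_slots: int = N_SLOTS

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def offset_row(self) -> int:
        """Index of the last non-padded row (end of ramp-down)."""
        return 3 * (self.n_label_phones + 1) + 2 - 1


def encode_phone(phone: str, inv: PhoneInventory) -> np.ndarray:
    """Return the binary feature code of ``phone`` (all ones for the segmentation character)."""
    if phone == inv.seg_symbol:
        return inv.seg_code
    try:
        idx = inv._index[phone]
    except KeyError:
        raise UnknownPhoneError(f"phone {phone!r} not in inventory") from None
    return inv.features[idx].copy()


def _interp(a: np.ndarray, b: np.ndarray) -> list[np.ndarray]:
    # two co-articulation rows; linear so equal endpoints stay constant,
    # and a 1->0 feature passes through 0.95 then 0.05 exactly
    return [0.95 * a + 0.05 * b, 0.05 * a + 0.95 * b]


def build_unfolding_matrix(
    label: Iterable[str],
    inv: PhoneInventory,
    n_slots: int = N_SLOTS,
    pad: bool = True,
) -> UnfoldingMatrix:
    """Build the dynamic unfolding matrix for a phone-sequence label.

    Row layout: 2 ramp-up rows (from silence), the first phone, then for
    each following phone — including the appended segmentation character —
    2 co-articulation rows and the phone row, finally 2 ramp-down rows
    (to silence).  A label of p phones yields 3(p+1)+2 rows; with
    ``pad=True`` zero rows extend it to 3·n_slots+2.
    """
    label = list(label)
    if not 1 <= len(label) <= n_slots - 1:
        raise LabelCapacityError(
            f"label of {len(label)} phones does not fit {n_slots} slots "
            "(segmentation character occupies one slot)"
        )
    codes = [encode_phone(p, inv) for p in label] + [inv.seg_code]
    zero = np.zeros(inv.n_features)
    rows: list[np.ndarray] = []
    rows.extend(_interp(zero, codes[0]))  # ramp-up from silence
    rows.append(codes[0])
    for prev, nxt in zip(codes, codes[1:]):
        rows.extend(_interp(prev, nxt))
        rows.append(nxt)
    rows.extend(_interp(codes[-1], zero))  # ramp-down to silence
    values = np.vstack(rows)
    if pad:
        total = 3 * n_slots + 2
        values = np.vstack([values, np.zeros((total - len(rows), inv.n_features))])
    return UnfoldingMatrix(values=values, n_label_phones=len(label), n_slots=n_slots)


def build_lexical_vector(
    label: Iterable[str], inv: PhoneInventory, n_slots: int = N_SLOTS
) -> np.ndarray:
    """Concatenate phone codes plus the segmentation code into n_slots·n_features entries."""
    label = list(label)
    if not 1 <= len(label) <= n_slots - 1:
        raise LabelCapacityError(
            f"label of {len(label)} phones does not fit {n_slots} slots"
        )
    parts = [encode_phone(p, inv) for p in label] + [inv.seg_code]
    vec = np.zeros(n_slots * inv.n_features)
    flat = np.concatenate(parts)
    vec[: flat.size] = flat
    return vec


def cohort_of(
    item: VocabularyItem,
    vocab: Sequence[VocabularyItem],
    n_onset_phones: int = 1,
) -> set[str]:
    """Ids of all vocabulary items sharing the first ``n_onset_phones`` phones with ``item``.

    The item itself is included, matching the convention that a cohort of
    size 1 means "no competitors".
    """
    key = item.label[:n_onset_phones]
    return {v.item_id for v in vocab if v.label[:n_onset_phones] == key}
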