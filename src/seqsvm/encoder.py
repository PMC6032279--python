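"""188-dimensional physicochemical sequence descriptor (CTD family).

Each protein sequence of length L maps to a fixed-length vector of four
concatenated blocks:

* **AAC** (20): per-residue frequency count(a)/L over the alphabet
  ACDEFGHIKLMNPQRSTVWY.
* **Composition** (24 = 8 properties × 3 groups): fraction of residues
  falling in each property group.
* **Transition** (24 = 8 × 3 group pairs): for each unordered group pair
  {j, k}, the number of adjacent residue pairs whose two members lie in
  different groups j and k, divided by L − 1.
* **Distribution** (120 = 8 × 3 × 5): for each property group, the
  sequence position (as a fraction of L) of the first, 25%-, 50%-,
  75%-quantile and last occurrence of a group member.  The q-quantile
  landmark is the ⌈q·c⌉-th of the c occurrences (minimum the 1st); an
  absent group yields five zeros.

Frequencies are emitted as fractions in [0, 1]; multiply by 100 for
percentage output.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from seqsvm.groups import AMINO_ACIDS, AA_INDEX, PropertyGroupTable
from seqsvm.io import LabeledDataset, ProteinRecord
from seqsvm.matrix import LabeledFeatureMatrix

#: within-property order of transition group pairs
_PAIRS = ((0, 1), (0, 2), (1, 2))
_LANDMARKS = ("first", "p25", "p50", "p75", "p100")


def feature_names(table: PropertyGroupTable | None = None) -> list[str]:
    """The frozen 188-entry feature-name list for ``table``."""
    table = table or PropertyGroupTable.default()
    names = [f"AAC_{aa}" for aa in AMINO_ACIDS]
    for prop in table.properties:
        names += [f"COMP_{prop}_g{j + 1}" for j in range(3)]
    for prop in table.properties:
        names += [f"TRANS_{prop}_g{j + 1}g{k + 1}" for j, k in _PAIRS]
    for prop in table.properties:
        for j in range(3):
            names += [f"DIST_{prop}_g{j + 1}_{lm}" for lm in _LANDMARKS]
    return names


def _as_indices(record: ProteinRecord | str) -> np.ndarray:
    seq = record.sequence if isinstance(record, ProteinRecord) else record.upper()
    return np.fromiter((AA_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))


def aac_composition(record: ProteinRecord | str) -> np.ndarray:
    """Amino-acid composition: count(a)/L in fixed alphabetical order."""
    idx = _as_indices(record)
    if idx.size == 0:
        raise ValueError("empty sequence")
    return np.bincount(idx, minlength=20) / idx.size


def group_composition(
    record: ProteinRecord | str, table: PropertyGroupTable | None = None
) -> np.ndarray:
    """Per-property group composition: |{t : s_t ∈ R_ij}| / L, 8×3 values."""
    table = table or PropertyGroupTable.default()
    idx = _as_indices(record)
    if idx.size == 0:
        raise ValueError("empty sequence")
    out = np.empty(24)
    for i, prop in enumerate(table.properties):
        gidx = np.asarray(table.group_index(prop), dtype=np.intp)[idx]
        out[3 * i : 3 * i + 3] = np.bincount(gidx, minlength=3) / idx.size
    return out


def group_transition(
    record: ProteinRecord | str, table: PropertyGroupTable | None = None
) -> np.ndarray:
    """Bivalent transition frequencies between group pairs, 8×3 values.

    For property i and unordered pair {j, k}: the count of adjacent
    positions (t, t+1) with one residue in group j and the other in
    group k, normalized by L − 1.  A single-residue sequence has no
    adjacent pairs; all values are 0.
    """
    table = table or PropertyGroupTable.default()
    idx = _as_indices(record)
    if idx.size == 0:
        raise ValueError("empty sequence")
    out = np.zeros(24)
    if idx.size < 2:
        return out
    denom = idx.size - 1
    for i, prop in enumerate(table.properties):
        gidx = np.asarray(table.group_index(prop), dtype=np.intp)[idx]
        a, b = gidx[:-1], gidx[1:]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        for p, (j, k) in enumerate(_PAIRS):
            out[3 * i + p] = np.count_nonzero((lo == j) & (hi == k)) / denom
    return out


def group_distribution(
    record: ProteinRecord | str, table: PropertyGroupTable | None = None
) -> np.ndarray:
    """Positional distribution landmarks, 8×3×5 values.

    For each property group with occurrence positions p_1 < ... < p_c
    (1-based), emits p_1/L, p_⌈0.25c⌉/L, p_⌈0.50c⌉/L, p_⌈0.75c⌉/L and
    p_c/L; five zeros if the group is absent.
    """
    table = table or PropertyGroupTable.default()
    idx = _as_indices(record)
    if idx.size == 0:
        raise ValueError("empty sequence")
    L = idx.size
    out = np.zeros(120)
    pos = np.arange(1, L + 1)
    for i, prop in enumerate(table.properties):
        gidx = np.asarray(table.group_index(prop), dtype=np.intp)[idx]
        for j in range(3):
            p = pos[gidx == j]
            c = p.size
            if c == 0:
                continue
            # ⌈q·c⌉-th occurrence, clamped to at least the 1st
            quart = [max(1, int(np.ceil(q * c))) for q in (0.25, 0.5, 0.75)]
            lms = [p[0], p[quart[0] - 1], p[quart[1] - 1], p[quart[2] - 1], p[-1]]
            out[15 * i + 5 * j : 15 * i + 5 * j + 5] = np.asarray(lms) / L
    return out


def encode_sequence(
    record: ProteinRecord | str, table: PropertyGroupTable | None = None
) -> np.ndarray:
    """Concatenate [AAC | composition | transition | distribution] → 188."""
    table = table or PropertyGroupTable.default()
    return np.concatenate(
        [
            aac_composition(record),
            group_composition(record, table),
            group_transition(record, table),
            group_distribution(record, table),
        ]
    )


def encode_dataset(
    dataset: LabeledDataset, table: PropertyGroupTable | None = None
) -> LabeledFeatureMatrix:
    """Encode every record of a labeled dataset into an n × 188 matrix."""
    table = table or PropertyGroupTable.default()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rows = []
    for rec in dataset.records:
        try:
            rows.append(encode_sequence(rec, table))
        except Exception as exc:  # surface the offending record
            raise ValueError(f"encoding failed for record {rec.id!r}: {exc}") from exc
    return LabeledFeatureMatrix(
        X=np.vstack(rows),
        y=np.asarray(dataset.labels),
        feature_names=feature_names(table),
        ids=[r.id for r in dataset.records],
    )


class CTDEncoder(BaseEstimator, TransformerMixin):
    """Transformer mapping protein sequences to 188D descriptors.

    Accepts an iterable of sequences (strings or :class:`ProteinRecord`)
    and returns an ``(n, 188)`` array.  Stateless: ``fit`` only validates
    the group table.

    Parameters
    ----------
    table : PropertyGroupTable, optional
        Property groupings; defaults to the standard CTD table with the
        secondary-structure grouping EALMQKRH / VIYCWFT / GNPSD.
    percent : bool, default False
        Emit percentages (×100) instead of fractions.
    """

    def __init__(
        self, table: PropertyGroupTable | None = None, percent: bool = False
    ):
        self.table = table
        self.percent = percent

    def _table(self) -> PropertyGroupTable:
        return self.table if self.table is not None else PropertyGroupTable.default()

    def fit(self, X: Iterable, y=None) -> "CTDEncoder":
        self._table()  # construction enforces the partition invariant
        self.n_features_out_ = 188
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        table = self._table()
        rows = [encode_sequence(rec, table) for rec in X]
        if not rows:
            raise ValueError("no sequences to encode")
        out = np.vstack(rows)
        return out * 100.0 if self.percent else out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(feature_names(self._table()), dtype=object)
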