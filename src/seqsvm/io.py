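"""Reading, validating and writing protein sequence data.

Sequences are restricted to the 20-letter standard amino-acid alphabet:
the encoder's property-group tables are defined only over those letters,
so records carrying ambiguity codes (B, X, Z, ...) are dropped, rejected
or coerced according to an explicit policy at parse time.

A labeled benchmark dataset S is the disjoint union of a positive subset
S+ (label +1) and a negative subset S- (label -1).  FASTA carries no
labels; class membership comes from which input file a record came from,
or from a two-column id/label TSV map.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from seqsvm.groups import AA_SET

Policy = Literal["reject", "drop", "coerce"]

#: letters treated as non-standard (ambiguity codes, rare residues, gaps)
NON_STANDARD = frozenset("BXZJOU*-.")


class SequenceError(ValueError):
    """Invalid sequence content or inconsistent dataset construction."""


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence.

    Attributes
    ----------
    id : str
        Record identifier (FASTA header up to first whitespace).
    sequence : str
        Upper-case sequence over the 20 standard amino-acid letters.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - AA_SET
        if bad:
            raise SequenceError(
                f"record {self.id!r}: non-standard letters {''.join(sorted(bad))!r}"
            )

    @property
    def L(self) -> int:
        """Sequence length."""
        return len(self.sequence)


@dataclass
class LabeledDataset:
    """Ordered records with parallel +1/-1 labels (S = S+ ∪ S-)."""

    records: list[ProteinRecord]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.records) != len(self.labels):
            raise SequenceError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        if any(lab not in (1, -1) for lab in self.labels):
            raise SequenceError("labels must be +1 or -1")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def positives(self) -> list[ProteinRecord]:
        return [r for r, y in zip(self.records, self.labels) if y == 1]

    @property
    def negatives(self) -> list[ProteinRecord]:
        return [r for r, y in zip(self.records, self.labels) if y == -1]


def read_fasta(
    path: str | Path, policy: Policy = "drop"
) -> tuple[list[ProteinRecord], int]:
    """Parse a FASTA file into validated :class:`ProteinRecord` objects.

    Parameters
    ----------
    path : path
        FASTA file (wrapped or unwrapped; case-insensitive).
    policy : {"reject", "drop", "coerce"}
        How to treat sequences containing non-standard letters
        (B, X, Z, J, O, U, ``*``, gaps): ``reject`` raises,
        ``drop`` omits the record, ``coerce`` strips the offending
        letters and keeps the remainder.

    Returns
    -------
    records, n_dropped
        Records in file order and the number of records dropped
        (always 0 under ``reject`` and ``coerce``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = list(SeqIO.parse(str(path), "fasta"))
    if not raw:
        raise SequenceError(f"{path}: no FASTA records found")

    seen: dict[str, int] = {}
    records: list[ProteinRecord] = []
    n_dropped = 0
    for rec in raw:
        rid = rec.id
        if rid in seen:
            seen[rid] += 1
            new_id = f"{rid}__dup{seen[rid]}"
            warnings.warn(
                f"duplicate id {rid!r}; keeping both, renaming to {new_id!r}",
                stacklevel=2,
            )
            rid = new_id
        else:
            seen[rid] = 0
        seq = str(rec.seq).upper()
        bad = set(seq) - AA_SET
        if bad:
            if policy == "reject":
                raise SequenceError(
                    f"record {rid!r}: non-standard letters "
                    f"{''.join(sorted(bad))!r} (policy=reject)"
                )
            if policy == "drop":
                n_dropped += 1
                continue
            seq = "".join(c for c in seq if c in AA_SET)
        if not seq:
            raise SequenceError(f"record {rid!r}: zero valid residues")
        if len(seq) < 2:
            warnings.warn(
                f"record {rid!r}: length {len(seq)} < 2; transition "
                "descriptors will be zero",
                stacklevel=2,
            )
        records.append(ProteinRecord(id=rid, sequence=seq))
    return records, n_dropped


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA with 60-column wrapped sequence lines."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)


def build_dataset(
    positives: Sequence[ProteinRecord], negatives: Sequence[ProteinRecord]
) -> LabeledDataset:
    """Assemble a labeled dataset: positives (label +1) then negatives (-1).

    Raises if both collections are empty or an id appears in both classes
    (contradictory label).
    """
    if not positives and not negatives:
        raise SequenceError("both classes empty")
    shared = {r.id for r in positives} & {r.id for r in negatives}
    if shared:
        raise SequenceError(
            f"ids in both classes (contradictory labels): {sorted(shared)}"
        )
    records = list(positives) + list(negatives)
    labels = [1] * len(positives) + [-1] * len(negatives)
    return LabeledDataset(records=records, labels=labels)


def read_label_map(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV ``id<TAB>label`` map.

    Labels may be ``1``/``-1`` or ``pos``/``neg`` (case-insensitive).
    """
    out: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise SequenceError(f"label map: expected 2 columns, got {row!r}")
            rid, lab = row[0].strip(), row[1].strip().lower()
            if lab in ("1", "+1", "pos", "positive"):
                out[rid] = 1
            elif lab in ("-1", "neg", "negative"):
                out[rid] = -1
            else:
                raise SequenceError(f"label map: unrecognized label {row[1]!r}")
    if not out:
        raise SequenceError(f"{path}: empty label map")
    return out


def dataset_from_label_map(
    records: Sequence[ProteinRecord], label_map: dict[str, int]
) -> LabeledDataset:
    """Split one record collection into classes via an id->label map."""
    missing = [r.id for r in records if r.id not in label_map]
    if missing:
        raise SequenceError(f"records without labels: {missing[:5]}")
    pos = [r for r in records if label_map[r.id] == 1]
    neg = [r for r in records if label_map[r.id] == -1]
    return build_dataset(pos, neg)
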