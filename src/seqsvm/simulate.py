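"""Synthetic labeled sequence datasets with controllable class separation.

Negative-class residues are drawn i.i.d. from a background frequency
table (uniform 1/20 by default); positive-class residues come from the
background with extra probability mass Δ shifted onto the residues of
chosen physicochemical property groups (and removed proportionally from
the rest), so the encoder's corresponding composition features separate
the classes by ≈Δ in expectation.  Optional pure-noise feature columns
(``NOISE_*``) appended at the matrix level give ground truth for
selector-recovery tests.

This emulates only the statistical structure the pipeline consumes
(compositional bias, class imbalance), not real antioxidant-protein
biology (motifs, domains, phylogenetic correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from seqsvm.groups import AMINO_ACIDS, AA_INDEX, PropertyGroupTable
from seqsvm.io import LabeledDataset, ProteinRecord, build_dataset
from seqsvm.matrix import LabeledFeatureMatrix
from seqsvm.encoder import encode_dataset


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration.

    bias_groups : list of (property, group, Δ)
        Composition shifts applied to the positive class; ``group`` is
        1-based (1..3).  Δ is added to the total probability of the
        group's residues and removed proportionally elsewhere.
    """

    n_pos: int = 30
    n_neg: int = 180
    length_range: tuple[int, int] = (50, 150)
    bias_groups: tuple[tuple[str, int, float], ...] = ()
    n_noise_features: int = 0
    seed: int = 0
    background: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        if self.n_pos < 0 or self.n_neg < 0 or self.n_pos + self.n_neg == 0:
            raise ValueError("need at least one sample")
        if self.background is not None:
            bg = np.asarray(self.background)
            if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
                raise ValueError("background must be 20 positive values summing to 1")


#: strong compositional shift — one group gains 0.30 probability mass
STRONG_SHIFT: tuple[tuple[str, int, float], ...] = (("charge", 1, 0.30),)
#: moderate shift — enough signal to classify, weak enough to err
MODERATE_SHIFT: tuple[tuple[str, int, float], ...] = (("charge", 1, 0.12),)


def class_probabilities(
    spec: SyntheticSpec, table: PropertyGroupTable | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Residue sampling distributions (negative, positive) for ``spec``."""
    table = table or PropertyGroupTable.default()
    bg = (
        np.asarray(spec.background, dtype=float)
        if spec.background is not None
        else np.full(20, 1.0 / 20.0)
    )
    pos = bg.copy()
    for prop, group, delta in spec.bias_groups:
        if prop not in table.groups:
            raise ValueError(f"unknown property {prop!r}")
        if group not in (1, 2, 3):
            raise ValueError(f"group must be 1..3, got {group}")
        members = np.array(
            [AA_INDEX[a] for a in table.groups[prop][group - 1].upper()]
        )
        in_mass = pos[members].sum()
        out_mask = np.ones(20, dtype=bool)
        out_mask[members] = False
        out_mass = pos[out_mask].sum()
        if in_mass + delta >= 1.0 or in_mass + delta <= 0.0:
            raise ValueError(f"infeasible shift Δ={delta} on {prop} group {group}")
        pos[members] *= (in_mass + delta) / in_mass
        pos[out_mask] *= (out_mass - delta) / out_mass
    if (pos <= 0).any() or (pos >= 1).any():
        raise ValueError("shift drives residue probabilities out of (0,1)")
    return bg, pos / pos.sum()


def _draw_class(
    rng: np.random.Generator,
    n: int,
    probs: np.ndarray,
    length_range: tuple[int, int],
    prefix: str,
) -> list[ProteinRecord]:
    lo, hi = length_range
    out = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(np.array(list(AMINO_ACIDS))[rng.choice(20, size=L, p=probs)])
        out.append(ProteinRecord(id=f"{prefix}{i:04d}", sequence=seq))
    return out


def generate_sequences(
    spec: SyntheticSpec, table: PropertyGroupTable | None = None
) -> LabeledDataset:
    """Draw a labeled dataset (positives then negatives), reproducible
    from ``spec.seed``."""
    table = table or PropertyGroupTable.default()
    bg, pos_probs = class_probabilities(spec, table)
    rng = np.random.default_rng(spec.seed)
    positives = _draw_class(rng, spec.n_pos, pos_probs, spec.length_range, "pos")
    negatives = _draw_class(rng, spec.n_neg, bg, spec.length_range, "neg")
    return build_dataset(positives, negatives)


def generate_matrix(
    spec: SyntheticSpec, table: PropertyGroupTable | None = None
) -> LabeledFeatureMatrix:
    """Encode a generated dataset; append ``spec.n_noise_features``
    i.i.d. uniform noise columns named ``NOISE_<i>``."""
    table = table or PropertyGroupTable.default()
    dataset = generate_sequences(spec, table)
    lfm = encode_dataset(dataset, table)
    if spec.n_noise_features > 0:
        # separate stream so the sequence draw is unaffected by n_noise_features
        rng = np.random.default_rng(
            np.random.SeedSequence(spec.seed, spawn_key=(1,))
        )
        noise = rng.uniform(size=(lfm.n_samples, spec.n_noise_features))
        lfm = LabeledFeatureMatrix(
            X=np.hstack([lfm.X, noise]),
            y=lfm.y,
            feature_names=list(lfm.feature_names)
            + [f"NOISE_{i}" for i in range(spec.n_noise_features)],
            ids=list(lfm.ids),
        )
    return lfm
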