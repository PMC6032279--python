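"""Sensitivity, specificity and accuracy from confusion counts.

Two equivalent bookkeeping conventions are maintained and cross-checked:
the TP/TN/FP/FN form (Sn = TP/(TP+FN), Sp = TN/(TN+FP),
Acc = (TP+TN)/total) and the class-total form built on N+ (number of
actual antioxidant/positive samples), N- (actual negatives), N-+
(positives misclassified as negative, i.e. FN) and N+- (negatives
mislabeled positive, i.e. FP), under which Sn = 1 - N-+/N+,
Sp = 1 - N+-/N- and Acc = 1 - (N-+ + N+-)/(N+ + N-).

The convention N+ = TP + FN (actual class totals) is the one that makes
the two forms algebraically identical; it is asserted on every call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

_IDENTITY_TOL = 1e-12


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with the class-total (N-form) bookkeeping derived."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total < 1:
            raise ValueError("confusion table is empty")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def N_plus(self) -> int:
        """Number of actual positive (antioxidant) samples."""
        return self.TP + self.FN

    @property
    def N_minus(self) -> int:
        """Number of actual negative (non-antioxidant) samples."""
        return self.TN + self.FP

    @property
    def N_minus_plus(self) -> int:
        """Positives misclassified as negative (= FN)."""
        return self.FN

    @property
    def N_plus_minus(self) -> int:
        """Negatives mislabeled as positive (= FP)."""
        return self.FP

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.TN + other.TN,
            self.FP + other.FP,
            self.FN + other.FN,
        )


@dataclass(frozen=True)
class MetricReport:
    """Sn, Sp, Acc in [0, 1]; NaN marks an undefined one-class ratio."""

    Sn: float
    Sp: float
    Acc: float

    def as_dict(self, counts: ConfusionCounts | None = None) -> dict:
        out: dict = {}
        if counts is not None:
            out.update(TP=counts.TP, TN=counts.TN, FP=counts.FP, FN=counts.FN)
        out.update(Sn=self.Sn, Sp=self.Sp, Acc=self.Acc)
        return out


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Compute Sn, Sp, Acc and assert the two-form identity.

    If a class is absent (TP+FN = 0 or TN+FP = 0) the undefined ratio is
    reported as NaN with a warning; Acc is still computed.
    """
    n_pos, n_neg = counts.N_plus, counts.N_minus

    if n_pos >= 1:
        sn = counts.TP / n_pos
        sn_alt = 1.0 - counts.N_minus_plus / n_pos
        if abs(sn - sn_alt) > _IDENTITY_TOL:
            raise AssertionError("Sn forms disagree")  # pragma: no cover
    else:
        warnings.warn("no positive samples: Sn undefined", stacklevel=2)
        sn = math.nan

    if n_neg >= 1:
        sp = counts.TN / n_neg
        sp_alt = 1.0 - counts.N_plus_minus / n_neg
        if abs(sp - sp_alt) > _IDENTITY_TOL:
            raise AssertionError("Sp forms disagree")  # pragma: no cover
    else:
        warnings.warn("no negative samples: Sp undefined", stacklevel=2)
        sp = math.nan

    acc = (counts.TP + counts.TN) / counts.total
    acc_alt = 1.0 - (counts.N_minus_plus + counts.N_plus_minus) / (n_pos + n_neg)
    if abs(acc - acc_alt) > _IDENTITY_TOL:
        raise AssertionError("Acc forms disagree")  # pragma: no cover

    return MetricReport(Sn=sn, Sp=sp, Acc=acc)


def counts_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Confusion counts from parallel +1/-1 truth and prediction vectors."""
    import numpy as np

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == -1) & (y_pred == -1))),
        FP=int(np.sum((y_true == -1) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == -1))),
    )
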