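"""Class balancing: SMOTE oversampling, majority undersampling,
standardization.

SMOTE creates synthetic minority samples on the line segments joining
each minority sample to its k nearest minority neighbors (Euclidean
metric): at an oversampling rate of r% (r a multiple of 100), r/100
distinct neighbors are drawn without replacement per minority sample and
each synthetic point is x + u·(z − x) with u uniform on [0, 1].  Data
are standardized (zero mean, unit variance per column) after balancing.

In cross-validated evaluation, balancing and standardization are refit
inside each training partition by default (``smote_scope="fold"``) so no
information about held-out samples leaks into preprocessing; the
``"global"`` scope applies them once to the full dataset before
splitting, which reproduces protocols that balance first and
cross-validate after, at the cost of optimistic bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import pairwise_distances

from seqsvm.matrix import LabeledFeatureMatrix


@dataclass(frozen=True)
class SmoteConfig:
    """SMOTE parameters.

    k : nearest minority neighbors considered per sample.
    rate : oversampling percentage; a multiple of 100 (rate/100 synthetic
        samples per minority sample), 0 disables oversampling, or "auto"
        to approach parity with the majority class (capped at 100·k).
    majority_undersample : fraction of majority samples retained.
    seed : RNG seed for neighbor choice and interpolation.
    """

    k: int = 5
    rate: int | str = "auto"
    majority_undersample: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if isinstance(self.rate, str):
            if self.rate != "auto":
                raise ValueError(f"rate must be an integer or 'auto', got {self.rate!r}")
        elif self.rate < 0 or self.rate % 100 != 0:
            raise ValueError(
                f"rate must be a non-negative multiple of 100, got {self.rate}"
            )
        if not 0.0 < self.majority_undersample <= 1.0:
            raise ValueError("majority_undersample must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticSample:
    """Provenance of one synthetic point (for the convexity audit)."""

    parent_index: int
    neighbor_index: int
    u: float


def auto_rate(n_minority: int, n_majority: int, k: int) -> int:
    """Oversampling rate approaching class parity: 100·round(n_maj/n_min − 1),
    capped at 100·k (each minority sample has only k usable neighbors)."""
    r = 100 * round(n_majority / n_minority - 1)
    return int(min(max(r, 0), 100 * k))


def _minority_label(y: np.ndarray) -> int:
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    # ties: treat the positive class as minority (the class of interest)
    return 1 if n_pos <= n_neg else -1


def smote_oversample(
    X: LabeledFeatureMatrix, cfg: SmoteConfig
) -> tuple[LabeledFeatureMatrix, list[SyntheticSample]]:
    """Append synthetic minority samples; returns the augmented matrix and
    a provenance log (parent row, neighbor row, interpolation weight).

    Synthetic count is (rate/100)·n_minority; original rows are kept
    verbatim and synthetics carry ids ``synthetic_<parent_id>_<n>``.
    """
    y = X.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    min_lab = _minority_label(y)
    min_idx = np.flatnonzero(y == min_lab)
    maj_idx = np.flatnonzero(y != min_lab)
    n_min = min_idx.size

    rate = (
        auto_rate(n_min, maj_idx.size, cfg.k)
        if cfg.rate == "auto"
        else int(cfg.rate)
    )
    if rate == 0:
        return X, []
    n_per = rate // 100
    if n_min < cfg.k + 1:
        raise ValueError(
            f"minority class has {n_min} samples; need at least k+1 = {cfg.k + 1}"
        )
    if n_per > cfg.k:
        raise ValueError(f"rate {rate}% needs {n_per} neighbors but k={cfg.k}")

    Xm = X.X[min_idx]
    D = pairwise_distances(Xm)
    np.fill_diagonal(D, np.inf)
    rng = np.random.default_rng(cfg.seed)

    rows, ids, log = [], [], []
    for local_i, global_i in enumerate(min_idx):
        # k nearest minority neighbors; ties broken by lower row index
        # (stable argsort on the distance row)
        nn_local = np.argsort(D[local_i], kind="stable")[: cfg.k]
        chosen = rng.choice(nn_local, size=n_per, replace=False)
        for n, local_j in enumerate(chosen):
            global_j = int(min_idx[local_j])
            u = float(rng.uniform())
            x, z = X.X[global_i], X.X[global_j]
            rows.append(x + u * (z - x))
            ids.append(f"synthetic_{X.ids[global_i]}_{n}")
            log.append(SyntheticSample(int(global_i), global_j, u))

    out = LabeledFeatureMatrix(
        X=np.vstack([X.X, np.array(rows)]),
        y=np.concatenate([y, np.full(len(rows), min_lab, dtype=int)]),
        feature_names=list(X.feature_names),
        ids=list(X.ids) + ids,
    )
    return out, log


def undersample_majority(
    X: LabeledFeatureMatrix, fraction: float, seed: int = 0
) -> LabeledFeatureMatrix:
    """Keep a uniform random subset of round(fraction·n_majority) majority
    rows; the minority class is untouched.  fraction=1.0 is the identity
    up to row order (rows are re-sorted by original index)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    y = X.y
    min_lab = _minority_label(y)
    maj_idx = np.flatnonzero(y != min_lab)
    n_keep = int(round(fraction * maj_idx.size))
    if n_keep < 1:
        raise ValueError("undersampling would leave no majority samples")
    rng = np.random.default_rng(seed)
    keep = rng.choice(maj_idx, size=n_keep, replace=False)
    all_keep = np.sort(np.concatenate([np.flatnonzero(y == min_lab), keep]))
    return X.subset_rows(all_keep)


def standardize(
    X: LabeledFeatureMatrix,
    stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[LabeledFeatureMatrix, tuple[np.ndarray, np.ndarray]]:
    """Column-wise (x − mean)/std.

    ``stats=None`` (fit mode) computes mean/std from the input;
    otherwise the supplied ``(mean, std)`` are applied unchanged (use
    train-fold stats on held-out data).  Zero-variance columns pass
    through unchanged, recorded as mean 0, std 1.
    """
    if stats is None:
        mean = X.X.mean(axis=0)
        std = X.X.std(axis=0, ddof=0)
        zero = std == 0.0
        mean = np.where(zero, 0.0, mean)
        std = np.where(zero, 1.0, std)
    else:
        mean, std = stats
        if mean.shape[0] != X.n_features or std.shape[0] != X.n_features:
            raise ValueError("stats dimension does not match feature count")
    out = LabeledFeatureMatrix(
        X=(X.X - mean) / std,
        y=X.y.copy(),
        feature_names=list(X.feature_names),
        ids=list(X.ids),
    )
    return out, (mean, std)


class SMOTEBalancer(BaseEstimator):
    """Resampler with an imbalanced-learn-style ``fit_resample`` API.

    Parameters mirror :class:`SmoteConfig`; ``fit_resample(X, y)``
    returns the augmented ``(X, y)`` arrays and records the synthetic-
    sample provenance in ``synthetic_log_``.
    """

    def __init__(
        self,
        k: int = 5,
        rate: int | str = "auto",
        majority_undersample: float = 1.0,
        random_state: int = 0,
    ):
        self.k = k
        self.rate = rate
        self.majority_undersample = majority_undersample
        self.random_state = random_state

    def fit_resample(self, X, y) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        lfm = LabeledFeatureMatrix(
            X=X, y=y, feature_names=[f"f{i}" for i in range(X.shape[1])]
        )
        cfg = SmoteConfig(
            k=self.k,
            rate=self.rate,
            majority_undersample=self.majority_undersample,
            seed=self.random_state,
        )
        if cfg.majority_undersample < 1.0:
            lfm = undersample_majority(
                lfm, cfg.majority_undersample, seed=cfg.seed
            )
        out, log = smote_oversample(lfm, cfg)
        self.synthetic_log_ = log
        self.minority_label_ = _minority_label(y)
        return out.X, out.y
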