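"""Max-relevance-max-distance (MRMD) feature ranking.

Each feature i receives the score

    total_i = MR_i + MD_i

where MR_i is the *relevance*, the absolute Pearson correlation between
feature column i and the +1/-1 class-label vector, and MD_i is the
*distance* (non-redundancy), the mean over the other M - 1 feature
columns of the average of three pairwise dissimilarities: Euclidean
distance, cosine distance (1 - cosine similarity) and Tanimoto distance
(1 - Tanimoto coefficient).  Columns are min-max normalized to [0, 1]
before the distance computation so the unbounded Euclidean term and the
bounded similarity terms are commensurable.  Features are ranked by
total score, descending, ties broken by lower original index.

A high MR means the feature tracks the class; a high MD means it is far
from (not redundant with) the other features.  Keeping the top-m
features removes redundancy while preserving label signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from seqsvm.matrix import LabeledFeatureMatrix


@dataclass(frozen=True)
class MrmdScores:
    """Per-feature relevance/distance components (all length M)."""

    MR: np.ndarray
    ED: np.ndarray
    COS: np.ndarray
    TC: np.ndarray
    MD: np.ndarray
    total: np.ndarray


@dataclass(frozen=True)
class FeatureRanking:
    """Permutation of feature indices by descending total score."""

    order: np.ndarray
    scores: MrmdScores

    def top(self, m: int) -> np.ndarray:
        return self.order[:m]


def pearson_correlation(x, y) -> float:
    """Product-moment correlation; 0 by convention if either input is
    constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        return 0.0
    return float((xc * yc).sum() / denom)


def relevance_scores(X, y=None) -> np.ndarray:
    """MR_i = |PCC(feature column i, label vector)| for every feature."""
    if isinstance(X, LabeledFeatureMatrix):
        X, y = X.X, X.y
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    return np.array([abs(pearson_correlation(X[:, i], y)) for i in range(X.shape[1])])


def _minmax(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span = np.where(span == 0.0, 1.0, span)
    return (X - lo) / span


def distance_scores(
    X, md_orientation: str = "distance"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean pairwise Euclidean / cosine / Tanimoto components per feature.

    Columns are min-max normalized to [0, 1] first.  With the default
    ``md_orientation="distance"``, cosine and Tanimoto similarities are
    converted to dissimilarities as 1 - s; ``"similarity"`` keeps the
    raw similarity means (the literal printed-formula reading).

    Returns ``(ED, COS, TC, MD)`` with ``MD = (ED + COS + TC) / 3``.
    """
    if md_orientation not in ("distance", "similarity"):
        raise ValueError(f"unknown md_orientation {md_orientation!r}")
    if isinstance(X, LabeledFeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    M = X.shape[1]
    if M < 2:
        raise ValueError("need at least 2 feature columns")
    F = _minmax(X)

    # pairwise Euclidean distances between columns
    G = F.T @ F  # (M, M) Gram matrix of columns
    sq = np.diag(G)
    d2 = sq[:, None] + sq[None, :] - 2.0 * G
    ed_pair = np.sqrt(np.maximum(d2, 0.0))

    norms = np.sqrt(sq)
    zero = norms == 0.0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-norm feature column(s): cosine/Tanimoto "
            "similarity terms set to 0",
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, norms)
    cos_sim = G / (safe[:, None] * safe[None, :])
    tani_denom = sq[:, None] + sq[None, :] - G
    tani_denom = np.where(tani_denom == 0.0, 1.0, tani_denom)
    tani_sim = G / tani_denom
    # zero-norm columns have undefined similarity: define as 0
    for sim in (cos_sim, tani_sim):
        sim[zero, :] = 0.0
        sim[:, zero] = 0.0

    off = ~np.eye(M, dtype=bool)
    ED = ed_pair[off].reshape(M, M - 1).mean(axis=1)
    if md_orientation == "distance":
        COS = (1.0 - cos_sim)[off].reshape(M, M - 1).mean(axis=1)
        TC = (1.0 - tani_sim)[off].reshape(M, M - 1).mean(axis=1)
    else:
        COS = cos_sim[off].reshape(M, M - 1).mean(axis=1)
        TC = tani_sim[off].reshape(M, M - 1).mean(axis=1)
    MD = (ED + COS + TC) / 3.0
    return ED, COS, TC, MD


def rank_features(
    X, y=None, md_orientation: str = "distance"
) -> FeatureRanking:
    """Rank all features by MR + MD, descending (ties: lower index)."""
    if isinstance(X, LabeledFeatureMatrix):
        X, y = X.X, X.y
    MR = relevance_scores(X, y)
    ED, COS, TC, MD = distance_scores(X, md_orientation=md_orientation)
    total = MR + MD
    order = np.lexsort((np.arange(total.size), -total))
    return FeatureRanking(
        order=order,
        scores=MrmdScores(MR=MR, ED=ED, COS=COS, TC=TC, MD=MD, total=total),
    )


def select_top(
    X: LabeledFeatureMatrix, ranking: FeatureRanking, m: int
) -> LabeledFeatureMatrix:
    """Restrict the matrix to the top-m ranked features (in rank order)."""
    if not 1 <= m <= X.n_features:
        raise ValueError(f"m={m} outside [1, {X.n_features}]")
    return X.select_columns(ranking.top(m))


def choose_m_by_cv(
    X: LabeledFeatureMatrix,
    ranking: FeatureRanking,
    grid,
    folds: int = 5,
    seed: int = 0,
    C: float = 8.0,
    gamma="scale",
) -> int:
    """Pick the feature count m from ``grid`` maximizing mean stratified
    k-fold accuracy of the downstream RBF-SVM; ties go to the smallest m.
    """
    from sklearn.model_selection import StratifiedKFold
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    grid = sorted(set(int(m) for m in grid))
    if not grid:
        raise ValueError("empty grid")
    if grid[0] < 1 or grid[-1] > X.n_features:
        raise ValueError(f"grid values outside [1, {X.n_features}]")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_m, best_acc = grid[0], -1.0
    for m in grid:
        cols = ranking.top(m)
        Xm = X.X[:, cols]
        accs = []
        for tr, te in skf.split(Xm, X.y):
            clf = make_pipeline(StandardScaler(), SVC(C=C, gamma=gamma))
            clf.fit(Xm[tr], X.y[tr])
            accs.append(float(np.mean(clf.predict(Xm[te]) == X.y[te])))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_m, best_acc = m, acc
    return best_m


class MRMDSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector implementing the MRMD ranking.

    Parameters
    ----------
    n_features : int or None, default None
        Number of top-ranked features to retain; ``None`` keeps all
        (ranking still computed).
    md_orientation : {"distance", "similarity"}, default "distance"
        Whether cosine/Tanimoto terms enter as dissimilarities (1 - s)
        or as raw similarities.

    Attributes
    ----------
    ranking_ : FeatureRanking
        Full ranking with per-feature score components.
    scores_ : ndarray of shape (M,)
        The MR + MD total per feature.

    Notes
    -----
    ``transform`` follows scikit-learn selector semantics: retained
    columns keep their original order.  Use :func:`select_top` for
    output in rank order.
    """

    def __init__(self, n_features: int | None = None, md_orientation: str = "distance"):
        self.n_features = n_features
        self.md_orientation = md_orientation

    def fit(self, X, y) -> "MRMDSelector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.ranking_ = rank_features(X, y, md_orientation=self.md_orientation)
        self.scores_ = self.ranking_.scores.total
        self.n_features_in_ = X.shape[1]
        m = self.n_features if self.n_features is not None else X.shape[1]
        if not 1 <= m <= X.shape[1]:
            raise ValueError(f"n_features={m} outside [1, {X.shape[1]}]")
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[self.ranking_.top(m)] = True
        self.support_mask_ = mask
        return self

    def _get_support_mask(self) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "support_mask_")
        return self.support_mask_


def scores_table(ranking: FeatureRanking, feature_names) -> "object":
    """Scores as a pandas DataFrame (feature, MR, ED, COS, TC, MD, total,
    rank), ordered by rank — the export format for score TSVs."""
    import pandas as pd

    s = ranking.scores
    rank_of = np.empty(len(ranking.order), dtype=int)
    rank_of[ranking.order] = np.arange(1, len(ranking.order) + 1)
    df = pd.DataFrame(
        {
            "feature_name": list(feature_names),
            "MR": s.MR,
            "ED": s.ED,
            "COS": s.COS,
            "TC": s.TC,
            "MD": s.MD,
            "total": s.total,
            "rank": rank_of,
        }
    )
    return df.sort_values("rank").reset_index(drop=True)
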