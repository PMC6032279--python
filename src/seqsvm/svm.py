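"""RBF-kernel support vector classification and cross-validated
evaluation.

The classifier is a maximum-margin SVM with radial-basis kernel
K(x, x') = exp(-γ‖x − x'‖²); the regularization parameter C and kernel
width γ are tunable by grid search.  Evaluation is by jackknife
(leave-one-out) or stratified k-fold cross-validation; with all
randomness seeded, the jackknife yields a unique result for a given
dataset and configuration.

All preprocessing (feature selection, SMOTE balancing, standardization)
is refit inside each training partition under the default leak-free
protocol; see :mod:`seqsvm.smote` for the scope switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from seqsvm._version import __version__ as _pkg_version
from seqsvm.matrix import LabeledFeatureMatrix
from seqsvm.metrics import ConfusionCounts, MetricReport, compute_metrics, counts_from_predictions
from seqsvm.mrmd import rank_features, select_top
from seqsvm.smote import SmoteConfig, smote_oversample, standardize

DEFAULT_C_GRID = tuple(2.0**p for p in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**p for p in range(-15, 4, 2))


@dataclass(frozen=True)
class SvmConfig:
    """SVM hyperparameters and tuning grids."""

    C: float = 8.0
    gamma: float | str = "scale"
    C_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("grids must be non-empty")
        if any(c <= 0 for c in self.C_grid):
            raise ValueError("C grid values must be positive")
        if any(g <= 0 for g in self.gamma_grid):
            raise ValueError("gamma grid values must be positive")


class RBFSeqClassifier(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVM with a feature-name contract.

    When fitted with named features, ``predict`` refuses matrices whose
    feature names do not match the training names in order — guarding
    against silently permuted or truncated columns.

    Parameters
    ----------
    C : float, default 8.0
        Regularization strength (inverse of margin softness).
    gamma : float or "scale", default "scale"
        RBF kernel width; "scale" uses 1 / (m · Var[X]).
    """

    def __init__(self, C: float = 8.0, gamma: float | str = "scale"):
        self.C = C
        self.gamma = gamma

    def fit(self, X, y, feature_names=None) -> "RBFSeqClassifier":
        if isinstance(X, LabeledFeatureMatrix):
            feature_names = feature_names or list(X.feature_names)
            X, y = X.X, X.y
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        self.feature_names_in_ = list(feature_names) if feature_names else None
        self.svc_ = SVC(C=self.C, gamma=self.gamma, kernel="rbf")
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        return self

    def _check_names(self, feature_names) -> None:
        if self.feature_names_in_ is not None and feature_names is not None:
            if list(feature_names) != self.feature_names_in_:
                raise ValueError(
                    "feature names/order differ from those seen at fit time"
                )

    def predict(self, X, feature_names=None) -> np.ndarray:
        if isinstance(X, LabeledFeatureMatrix):
            feature_names = feature_names or list(X.feature_names)
            X = X.X
        self._check_names(feature_names)
        return self.svc_.predict(np.asarray(X, dtype=float))

    def decision_function(self, X) -> np.ndarray:
        if isinstance(X, LabeledFeatureMatrix):
            X = X.X
        return self.svc_.decision_function(np.asarray(X, dtype=float))


def grid_search(X: LabeledFeatureMatrix, cfg: SvmConfig) -> tuple[float, float]:
    """Grid-search (C, γ) by mean stratified inner-CV accuracy.

    Standardization is refit inside each inner fold.  Ties resolve to
    the smaller C, then the smaller γ.
    """
    if cfg.inner_folds < 2:
        raise ValueError("inner_folds must be >= 2")
    skf = StratifiedKFold(
        n_splits=cfg.inner_folds, shuffle=True, random_state=cfg.seed
    )
    splits = list(skf.split(X.X, X.y))
    best = None
    for C in sorted(cfg.C_grid):
        for g in sorted(cfg.gamma_grid):
            accs = []
            for tr, te in splits:
                tr_m, stats = standardize(X.subset_rows(tr))
                te_m, _ = standardize(X.subset_rows(te), stats=stats)
                clf = SVC(C=C, gamma=g, kernel="rbf").fit(tr_m.X, tr_m.y)
                accs.append(float(np.mean(clf.predict(te_m.X) == te_m.y)))
            acc = float(np.mean(accs))
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, g)
    return best[1], best[2]


def train(
    X: LabeledFeatureMatrix, C: float = 8.0, gamma: float | str = "scale"
) -> RBFSeqClassifier:
    """Fit an RBF-SVM on a labeled feature matrix."""
    return RBFSeqClassifier(C=C, gamma=gamma).fit(X, X.y)


@dataclass(frozen=True)
class PipelineSpec:
    """Preprocessing + classifier configuration for evaluation loops.

    ``select_m=None`` disables feature selection; ``smote=False``
    disables balancing.  ``smote_scope`` chooses between refitting the
    balancer inside every training partition ("fold", leak-free) and
    balancing the full dataset once before splitting ("global").
    """

    select_m: int | None = None
    smote: bool = False
    smote_k: int = 5
    smote_rate: int | str = "auto"
    smote_scope: str = "fold"
    C: float = 8.0
    gamma: float | str = "scale"
    md_orientation: str = "distance"

    def __post_init__(self) -> None:
        if self.smote_scope not in ("fold", "global"):
            raise ValueError("smote_scope must be 'fold' or 'global'")


@dataclass(frozen=True)
class EvaluationResult:
    counts: ConfusionCounts
    report: MetricReport
    y_true: np.ndarray
    y_pred: np.ndarray

    def as_dict(self) -> dict:
        return self.report.as_dict(self.counts)


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(fold,)).generate_state(1)[0] % (2**31))


def _preprocess_global(X: LabeledFeatureMatrix, spec: PipelineSpec, seed: int) -> LabeledFeatureMatrix:
    if spec.select_m is not None:
        ranking = rank_features(X, md_orientation=spec.md_orientation)
        X = select_top(X, ranking, spec.select_m)
    if spec.smote:
        X, _ = smote_oversample(
            X, SmoteConfig(k=spec.smote_k, rate=spec.smote_rate, seed=seed)
        )
    X, _ = standardize(X)
    return X


def _evaluate_splits(
    X: LabeledFeatureMatrix,
    splits: list[tuple[np.ndarray, np.ndarray]],
    spec: PipelineSpec,
    seed: int,
    preprocessed: bool,
) -> EvaluationResult:
    n = X.n_samples
    y_pred = np.zeros(n, dtype=int)
    covered = np.zeros(n, dtype=bool)
    for fold, (tr, te) in enumerate(splits):
        tr_m = X.subset_rows(tr)
        te_m = X.subset_rows(te)
        if not preprocessed:
            if spec.select_m is not None:
                ranking = rank_features(tr_m, md_orientation=spec.md_orientation)
                tr_m = select_top(tr_m, ranking, spec.select_m)
                te_m = te_m.select_columns(ranking.top(spec.select_m))
            if spec.smote:
                tr_m, _ = smote_oversample(
                    tr_m,
                    SmoteConfig(
                        k=spec.smote_k,
                        rate=spec.smote_rate,
                        seed=_fold_seed(seed, fold),
                    ),
                )
            tr_m, stats = standardize(tr_m)
            te_m, _ = standardize(te_m, stats=stats)
        if len(np.unique(tr_m.y)) < 2:
            raise ValueError(f"training fold {fold} collapsed to one class")
        clf = SVC(C=spec.C, gamma=spec.gamma, kernel="rbf").fit(tr_m.X, tr_m.y)
        y_pred[te] = clf.predict(te_m.X)
        covered[te] = True
    assert covered.all()
    counts = counts_from_predictions(X.y, y_pred)
    return EvaluationResult(
        counts=counts,
        report=compute_metrics(counts),
        y_true=X.y.copy(),
        y_pred=y_pred,
    )


def jackknife_evaluate(
    X: LabeledFeatureMatrix, spec: PipelineSpec = PipelineSpec(), seed: int = 0
) -> EvaluationResult:
    """Leave-one-out evaluation: each sample is predicted by a model
    fitted (with all preprocessing) on the other n − 1 samples.

    With the seed fixed, the output is unique for a given dataset and
    configuration.
    """
    if X.n_samples < 3:
        raise ValueError("jackknife needs at least 3 samples")
    preprocessed = spec.smote_scope == "global"
    if preprocessed:
        X = _preprocess_global(X, spec, seed)
    n = X.n_samples
    splits = [
        (np.concatenate([np.arange(i), np.arange(i + 1, n)]), np.array([i]))
        for i in range(n)
    ]
    return _evaluate_splits(X, splits, spec, seed, preprocessed)


def kfold_evaluate(
    X: LabeledFeatureMatrix,
    folds: int,
    spec: PipelineSpec = PipelineSpec(),
    seed: int = 0,
) -> EvaluationResult:
    """Stratified k-fold evaluation with pooled out-of-fold predictions.

    ``folds == n`` reduces exactly to :func:`jackknife_evaluate`.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds == X.n_samples:
        return jackknife_evaluate(X, spec, seed)
    n_min = min(int(np.sum(X.y == 1)), int(np.sum(X.y == -1)))
    if folds > n_min:
        raise ValueError(f"folds={folds} exceeds minority class size {n_min}")
    preprocessed = spec.smote_scope == "global"
    if preprocessed:
        X = _preprocess_global(X, spec, seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = [(tr, te) for tr, te in skf.split(X.X, X.y)]
    return _evaluate_splits(X, splits, spec, seed, preprocessed)


# -- model persistence ------------------------------------------------

_ARCHIVE_VERSION = 1


def save_model(
    path,
    model: RBFSeqClassifier,
    preprocessing_stats=None,
    config: dict | None = None,
) -> None:
    """Persist a fitted model with its feature names, preprocessing stats
    and configuration in a versioned archive."""
    joblib.dump(
        {
            "archive_version": _ARCHIVE_VERSION,
            "package_version": _pkg_version,
            "model": model,
            "feature_names": model.feature_names_in_,
            "preprocessing_stats": preprocessing_stats,
            "config": config or {},
        },
        path,
    )


def load_model(path) -> dict:
    """Load a model archive; refuses incompatible archive versions."""
    data = joblib.load(path)
    if data.get("archive_version") != _ARCHIVE_VERSION:
        raise ValueError(
            f"incompatible model archive version {data.get('archive_version')!r}"
        )
    return data
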