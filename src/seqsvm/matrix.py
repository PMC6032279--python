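"""The labeled feature matrix passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class LabeledFeatureMatrix:
    """n samples × m features with parallel +1/-1 labels.

    Attributes
    ----------
    X : ndarray of shape (n, m)
        Feature values; no missing entries allowed.
    y : ndarray of shape (n,)
        Class labels in {+1, -1}.
    feature_names : list of str
        Column names, length m.
    ids : list of str
        Sample identifiers, length n.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} labels"
            )
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError(
                f"{len(self.feature_names)} feature names for "
                f"{self.X.shape[1]} columns"
            )
        if not self.ids:
            self.ids = [f"s{i}" for i in range(self.X.shape[0])]
        if len(self.ids) != self.X.shape[0]:
            raise ValueError("ids length must match sample count")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")
        extra = set(np.unique(self.y)) - {1, -1}
        if extra:
            raise ValueError(f"labels must be +1/-1, found {sorted(extra)}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select_columns(self, indices: Sequence[int]) -> "LabeledFeatureMatrix":
        idx = list(indices)
        return LabeledFeatureMatrix(
            X=self.X[:, idx],
            y=self.y.copy(),
            feature_names=[self.feature_names[i] for i in idx],
            ids=list(self.ids),
        )

    def subset_rows(self, indices: Sequence[int]) -> "LabeledFeatureMatrix":
        idx = list(indices)
        return LabeledFeatureMatrix(
            X=self.X[idx],
            y=self.y[idx],
            feature_names=list(self.feature_names),
            ids=[self.ids[i] for i in idx],
        )

    # -- persistence ---------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """TSV with header; first two columns are ``id`` and ``label``."""
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.y)
        df.insert(0, "id", self.ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabeledFeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        if list(df.columns[:2]) != ["id", "label"]:
            raise ValueError("TSV must start with columns 'id' and 'label'")
        return cls(
            X=df.iloc[:, 2:].to_numpy(dtype=float),
            y=df["label"].to_numpy(dtype=int),
            feature_names=list(df.columns[2:]),
            ids=[str(i) for i in df["id"]],
        )

    def to_libsvm(self, path: str | Path) -> None:
        """Sparse LIBSVM format: ``label index:value ...`` (1-based)."""
        with open(path, "w") as fh:
            for row, lab in zip(self.X, self.y):
                parts = [f"{lab:+d}"]
                parts += [
                    f"{j + 1}:{v:.10g}" for j, v in enumerate(row) if v != 0.0
                ]
                fh.write(" ".join(parts) + "\n")
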