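"""Labelled feature matrices and their tab-separated on-disk form.

The TSV layout is: first column ``id``, second ``label``, remaining columns
named features.  Values are written with 10 significant digits so a
write/read round trip is bit-stable at that precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class FeatureMatrix:
    """n samples x d named feature columns plus binary labels."""

    ids: list[str]
    y: np.ndarray
    feature_names: list[str]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, d = self.X.shape
        if len(self.ids) != n or self.y.shape != (n,):
            raise ValueError("ids, labels and X row count disagree")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length does not match X columns")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select(self, indices: np.ndarray) -> "FeatureMatrix":
        """A new matrix restricted to the given feature columns, in order."""
        indices = np.asarray(indices, dtype=np.int64)
        return FeatureMatrix(
            ids=list(self.ids),
            y=self.y.copy(),
            feature_names=[self.feature_names[i] for i in indices],
            X=self.X[:, indices].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.y)
        df.insert(0, "id", self.ids)
        return df


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature matrix not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if list(df.columns[:2]) != ["id", "label"]:
        raise ValueError("feature matrix must start with columns 'id' and 'label'")
    return FeatureMatrix(
        ids=df["id"].tolist(),
        y=df["label"].to_numpy(dtype=np.int64),
        feature_names=list(df.columns[2:]),
        X=df.iloc[:, 2:].to_numpy(dtype=float),
    )
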