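"""Labelled square matrices: CCI similarity and Bray-Curtis distance."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["LabeledMatrix", "SimilarityMatrix", "DistanceMatrix"]


class LabeledMatrix:
    """Square symmetric matrix with row/column labels."""

    def __init__(self, labels: Sequence[str], values: np.ndarray):
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise ValueError(f"values shape {values.shape} != ({len(labels)},) squared")
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        if np.any(np.isnan(values)):
            raise ValueError("matrix contains NaN")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError("matrix must be symmetric")
        self.labels = labels
        self.values = (values + values.T) / 2.0
        self._validate()

    def _validate(self) -> None:
        pass

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path, index_col=0)
        return cls(df.index.astype(str).tolist(), df.to_numpy())

    def reorder(self, labels: Sequence[str]):
        idx = [self.labels.index(l) for l in labels]
        return type(self)(list(labels), self.values[np.ix_(idx, idx)])

    def off_diagonal(self) -> np.ndarray:
        """All n(n-1) off-diagonal entries (both orientations)."""
        mask = ~np.eye(len(self), dtype=bool)
        return self.values[mask]


class SimilarityMatrix(LabeledMatrix):
    """Unit-diagonal similarity in [0, 1] (CCI)."""

    def _validate(self) -> None:
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("similarity matrix diagonal must be 1")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("similarity values must lie in [0, 1]")
        np.fill_diagonal(self.values, 1.0)
        np.clip(self.values, 0.0, 1.0, out=self.values)


class DistanceMatrix(LabeledMatrix):
    """Zero-diagonal nonnegative dissimilarity (Bray-Curtis, 1-CCI, ...)."""

    def _validate(self) -> None:
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be 0")
        if self.values.min() < -1e-9:
            raise ValueError("distances must be nonnegative")
        np.fill_diagonal(self.values, 0.0)
        np.clip(self.values, 0.0, None, out=self.values)
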