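"""Labeled symmetric distance matrices (shared by AMOVA, ordination, Mantel)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix with a zero diagonal and row/column labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("values shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("diagonal is not zero")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy squareform) order."""
        iu = np.triu_indices(len(self), k=1)
        return self.values[iu]

    def reorder(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))

    @classmethod
    def from_coordinates(cls, labels, coords: np.ndarray) -> "DistanceMatrix":
        from scipy.spatial.distance import pdist, squareform

        return cls(tuple(labels), squareform(pdist(np.asarray(coords, dtype=float))))
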