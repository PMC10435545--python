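"""Cross-session cell-registration maps.

Longitudinal analyses rely on a registration of cells between two imaging
sessions, as produced by probabilistic cell-registration tools.  The registry
lists matched cell-index pairs plus the spatial centroid of every cell in each
session; centroids support the closest-neighbor registration control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CellRegistry:
    """Registered cell pairs between session A and session B.

    Attributes
    ----------
    pairs
        Integer array ``(n_pairs, 2)``: columns are the cell index in session
        A and the matched cell index in session B.
    centroids_a, centroids_b
        ``(n_cells, 2)`` x/y centroid coordinates of every cell in each
        session (not just the registered ones, when available).
    """

    pairs: np.ndarray
    centroids_a: np.ndarray = field(default=None)
    centroids_b: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        for side in (0, 1):
            col = self.pairs[:, side]
            if col.size != np.unique(col).size:
                raise ValueError("each cell may appear in at most one pair")
        if self.centroids_a is not None:
            self.centroids_a = np.asarray(self.centroids_a, dtype=float)
        if self.centroids_b is not None:
            self.centroids_b = np.asarray(self.centroids_b, dtype=float)

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])

    def to_csv(self, path) -> None:
        """Write as CSV (cell_a, cell_b, x_a, y_a, x_b, y_b), one row per pair."""
        rows = {"cell_a": self.pairs[:, 0], "cell_b": self.pairs[:, 1]}
        if self.centroids_a is not None:
            rows["x_a"] = self.centroids_a[self.pairs[:, 0], 0]
            rows["y_a"] = self.centroids_a[self.pairs[:, 0], 1]
        if self.centroids_b is not None:
            rows["x_b"] = self.centroids_b[self.pairs[:, 1], 0]
            rows["y_b"] = self.centroids_b[self.pairs[:, 1], 1]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CellRegistry":
        """Read a pair CSV.  Centroid arrays are sized to the largest index
        present; cells absent from the file have NaN centroids."""
        df = pd.read_csv(path)
        pairs = df[["cell_a", "cell_b"]].to_numpy(dtype=np.int64)
        ca = cb = None
        if {"x_a", "y_a"}.issubset(df.columns):
            ca = np.full((pairs[:, 0].max() + 1, 2), np.nan)
            ca[pairs[:, 0]] = df[["x_a", "y_a"]].to_numpy(dtype=float)
        if {"x_b", "y_b"}.issubset(df.columns):
            cb = np.full((pairs[:, 1].max() + 1, 2), np.nan)
            cb[pairs[:, 1]] = df[["x_b", "y_b"]].to_numpy(dtype=float)
        return cls(pairs, ca, cb)
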