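"""In-memory expression-matrix container.

Rows are genes (or probes, proteins, ...); columns are samples or
conditions.  All clustering code operates on integer row indices into one
of these matrices, so clusters are cheap index sets and the numeric data
is never copied around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """An n x d numeric matrix with unique row identifiers.

    Parameters
    ----------
    values : ndarray of shape (n, d)
        Finite float values, genes in rows.
    row_ids : list of str
        Unique gene/probe identifiers, one per row.
    col_ids : list of str
        Sample/condition identifiers, one per column.
    """

    values: np.ndarray
    row_ids: list = field(default=None)
    col_ids: list = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("matrix must have at least one row and one column")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at row {bad[0]}, column {bad[1]}"
            )
        if self.row_ids is None:
            self.row_ids = [f"g{i}" for i in range(n)]
        if self.col_ids is None:
            self.col_ids = [f"s{j}" for j in range(d)]
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if len(self.row_ids) != n:
            raise ValueError("row_ids length does not match row count")
        if len(self.col_ids) != d:
            raise ValueError("col_ids length does not match column count")
        if len(set(self.row_ids)) != n:
            seen, dups = set(), []
            for r in self.row_ids:
                if r in seen:
                    dups.append(r)
                seen.add(r)
            raise ValueError(f"duplicate row identifiers: {sorted(set(dups))}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def rows(self, idx) -> np.ndarray:
        """Return the point coordinates for a set of row indices."""
        return self.values[np.asarray(idx, dtype=int)]

    def subset(self, idx) -> "ExpressionMatrix":
        """A new matrix restricted to the given rows (in the given order)."""
        idx = np.asarray(idx, dtype=int)
        return ExpressionMatrix(
            self.values[idx],
            [self.row_ids[i] for i in idx],
            list(self.col_ids),
        )

    def standardized(self) -> "ExpressionMatrix":
        """Row-standardize: each gene profile to mean 0, variance 1.

        Constant rows are left at 0 rather than dividing by zero.
        """
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        return ExpressionMatrix((self.values - mu) / sd, list(self.row_ids), list(self.col_ids))
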