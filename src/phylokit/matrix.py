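"""Symmetric pairwise distance matrices.

The in-memory container pairs an ordered taxon list with a dense symmetric
float array (zero diagonal). Saturated or undefined entries — distance
corrections evaluated outside their domain, or pairs with no overlapping
sites — are stored as NaN and must be substituted with a finite value before
tree building or binary serialization.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator

import numpy as np

from .errors import PhylokitError


class DistanceMatrix:
    def __init__(self, taxa: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(taxa)
        if values.shape != (n, n):
            raise PhylokitError(
                f"matrix shape {values.shape} does not match {n} taxa"
            )
        if len(set(taxa)) != n:
            raise PhylokitError("duplicate taxon identifiers in matrix")
        self.taxa = list(taxa)
        self.values = values

    @property
    def n(self) -> int:
        return len(self.taxa)

    @classmethod
    def from_upper_rows(cls, taxa: list[str], rows: Iterable[np.ndarray]) -> "DistanceMatrix":
        """Assemble from upper-triangle rows; row i holds entries (i, i+1..n-1)."""
        n = len(taxa)
        values = np.zeros((n, n))
        i = -1
        for i, row in enumerate(rows):
            row = np.asarray(row, dtype=float)
            if row.shape != (n - 1 - i,):
                raise PhylokitError(
                    f"row {i} has {row.size} entries, expected {n - 1 - i}"
                )
            values[i, i + 1 :] = row
            values[i + 1 :, i] = row
        if i != n - 2:
            raise PhylokitError(f"expected {n - 1} rows, got {i + 1}")
        return cls(taxa, values)

    def upper_rows(self) -> Iterator[np.ndarray]:
        for i in range(self.n - 1):
            yield self.values[i, i + 1 :].copy()

    def validate(self) -> None:
        if not np.allclose(np.diag(self.values), 0.0):
            raise PhylokitError("nonzero diagonal")
        finite = np.isfinite(self.values)
        if not np.array_equal(finite, finite.T):
            raise PhylokitError("asymmetric missing-value pattern")
        if not np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite, self.values, 0.0).T,
        ):
            raise PhylokitError("matrix is not symmetric")
        vals = self.values[finite]
        if vals.size and vals.min() < 0:
            raise PhylokitError("negative distance entry")

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def substitute_missing(self, value: float) -> "DistanceMatrix":
        """Replace NaN (saturated / no-overlap) entries with a fixed distance."""
        out = self.values.copy()
        out[np.isnan(out)] = value
        return DistanceMatrix(self.taxa, out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return self.taxa == other.taxa and np.array_equal(
            self.values, other.values, equal_nan=True
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"DistanceMatrix(n={self.n}, taxa={self.taxa[:3]}...)"
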