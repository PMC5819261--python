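"""Composite generalised Jaccard (CGJ) similarity and distance matrices.

The similarity between two genomes is the geometric mean of two
generalised Jaccard indices: J_p over their profile score signatures
and J_o over their GOM signatures,

    J = sqrt(J_p * J_o),   J_*(x, y) = sum_i min(x_i, y_i) / sum_i max(x_i, y_i),

and the dissimilarity is D = 1 - J.  Both lie in [0, 1]; two genomes
with no detectable similarity (disjoint supports) get J = 0, D = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotation import SignatureTable


def generalized_jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Sum of elementwise minima over sum of maxima; 0 when both are empty."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("entries must be nonnegative")
    denom = np.maximum(x, y).sum()
    if denom == 0:
        return 0.0
    return float(np.minimum(x, y).sum() / denom)


def cgj_similarity(jp: float, jo: float) -> float:
    """Geometric mean of the two generalised Jaccard indices."""
    if not (0 <= jp <= 1 and 0 <= jo <= 1):
        raise ValueError("Jaccard indices must lie in [0, 1]")
    return float(np.sqrt(jp * jo))


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")

    def __len__(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                fh.write(lab + "\t" + "\t".join(repr(float(v)) for v in self.values[i]) + "\n")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                fh.write(lab + "  " + "  ".join(f"{v:.6f}" for v in self.values[i]) + "\n")


def _gj_matrix(X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
    """Pairwise generalised Jaccard between rows of X (and rows of Y)."""
    X = np.asarray(X, dtype=float)
    Y = X if Y is None else np.asarray(Y, dtype=float)
    mins = np.minimum(X[:, None, :], Y[None, :, :]).sum(axis=2)
    maxs = np.maximum(X[:, None, :], Y[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(maxs > 0, mins / np.where(maxs > 0, maxs, 1.0), 0.0)
    return J


def cgj_matrix(table: SignatureTable, other: SignatureTable | None = None) -> np.ndarray:
    """Pairwise CGJ similarities between rows of one (or two) tables."""
    if other is not None:
        if (table.profile_ids != other.profile_ids
                or table.gom_labels != other.gom_labels):
            raise ValueError("tables are indexed against different databases")
    jp = _gj_matrix(table.pphmm, None if other is None else other.pphmm)
    jo = _gj_matrix(table.gom_sig, None if other is None else other.gom_sig)
    return np.sqrt(jp * jo)


def pairwise_distance_matrix(table: SignatureTable) -> DistanceMatrix:
    """D = 1 - CGJ over all rows of a signature table."""
    if len(table) < 2:
        raise ValueError("need at least two rows")
    D = 1.0 - cgj_matrix(table)
    np.fill_diagonal(D, 0.0)
    D = np.clip(0.5 * (D + D.T), 0.0, 1.0)  # symmetrise away float noise
    return DistanceMatrix(list(table.accessions), D)
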