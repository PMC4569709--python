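"""Unit-level mean repertoires and adjusted Bray-Curtis acoustic similarity.

Social units are compared by the weighted (abundance-weighted) Bray-Curtis
index between their mean coda-frequency vectors, adjusted to a similarity:
``1 - sum|x_i - y_i| / sum(x_i + y_i)``, which is 1 for identical repertoires
and 0 for repertoires with disjoint support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .demography import Population

__all__ = ["SimilarityMatrix", "unit_mean_repertoire", "bray_curtis_similarity", "similarity_matrix"]


@dataclass
class SimilarityMatrix:
    """Symmetric unit-by-unit similarity matrix with unit diagonal."""

    unit_ids: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.unit_ids):
            raise ValueError("similarity matrix must be square and match unit_ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    def reorder(self, order: list[int]) -> "SimilarityMatrix":
        """Return the matrix with rows/columns permuted consistently."""
        idx = np.asarray(order)
        return SimilarityMatrix(
            unit_ids=[self.unit_ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
        )


def unit_mean_repertoire(pop: Population, unit_id: int) -> np.ndarray:
    """Element-wise mean repertoire over all living members of one unit."""
    idx = np.flatnonzero(pop.unit_id == unit_id)
    if idx.size == 0:
        raise ValueError(f"unit {unit_id} is empty")
    return pop.repertoires[idx].mean(axis=0)


def bray_curtis_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Adjusted weighted Bray-Curtis similarity between two frequency vectors.

    Both vectors must be non-negative and not both all-zero (the index is
    undefined for two empty repertoires).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("repertoire vectors must have equal length")
    if x.min() < 0 or y.min() < 0:
        raise ValueError("repertoire frequencies must be non-negative")
    denom = float((x + y).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis similarity undefined for two all-zero vectors")
    return 1.0 - float(np.abs(x - y).sum()) / denom


def similarity_matrix(pop: Population) -> SimilarityMatrix:
    """Pairwise adjusted Bray-Curtis similarity between all social units."""
    unit_ids = sorted(pop.unit_clan)
    if len(unit_ids) < 2:
        raise ValueError("need at least two units to build a similarity matrix")
    means = np.vstack([unit_mean_repertoire(pop, uid) for uid in unit_ids])
    if np.any(means.sum(axis=1) == 0):
        raise ValueError("a unit has an all-zero mean repertoire")
    sim = 1.0 - squareform(pdist(means, metric="braycurtis"))
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(unit_ids=unit_ids, values=np.clip(sim, 0.0, 1.0))
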