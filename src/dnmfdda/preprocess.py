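"""Similarity fusion, weighted-KNN densification, integrated matrices, Laplacians.

The model consumes one fused similarity per entity type (the element-wise
average of the available similarity sources), an association matrix whose
empty rows have optionally been filled by a rank-decayed, similarity-weighted
average of the k most similar rows (the cold-start preprocessing), the
horizontal concatenation of the two ([S | A-block], the integrated matrix),
and the unnormalized graph Laplacian L = U − S of each fused similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io_formats import AlignmentError, LabeledMatrix

__all__ = [
    "FusedSimilarity",
    "GraphLaplacian",
    "IntegratedMatrix",
    "fuse_similarities",
    "knn_fill",
    "build_integrated",
    "build_laplacian",
]

logger = logging.getLogger(__name__)

EntityView = Literal["drug", "disease"]


@dataclass
class FusedSimilarity:
    """A square symmetric similarity matrix in [0, 1] for one entity type."""

    values: np.ndarray
    ids: list[str]
    entity: EntityView

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("fused similarity must be square")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fused similarity contains non-finite values")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-12:
            raise ValueError("fused similarity must be symmetric within 1e-12")


@dataclass
class GraphLaplacian:
    """Degree-minus-similarity matrix; every row sums to zero."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.abs(self.values.sum(axis=1)).max(initial=0.0) > 1e-9:
            raise ValueError("Laplacian rows must sum to 0 within 1e-9")


@dataclass
class IntegratedMatrix:
    """[similarity | association] block matrix for one entity view.

    ``sim_width`` records where the similarity block ends; the drug view is
    m×(m+n) and the disease view is n×(n+m) (association block transposed).
    """

    values: np.ndarray
    sim_width: int
    view: EntityView

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min(initial=0.0) < 0:
            raise ValueError("integrated matrix must be nonnegative")


def fuse_similarities(mats: list[LabeledMatrix], entity: EntityView = "drug") -> FusedSimilarity:
    """Element-wise mean of the given similarity matrices, re-symmetrized.

    All matrices must share shape and id order (use
    :meth:`LabeledMatrix.reindex` or :func:`dnmfdda.load_bundle` first).
    """
    if not mats:
        raise ValueError("need at least one similarity matrix to fuse")
    first = mats[0]
    for m in mats[1:]:
        if m.shape != first.shape or m.row_ids != first.row_ids or m.col_ids != first.col_ids:
            raise AlignmentError("similarity matrices differ in shape or id order")
    mean = np.mean([m.values for m in mats], axis=0)
    mean = (mean + mean.T) / 2.0
    return FusedSimilarity(mean, list(first.row_ids), entity)


def knn_fill(
    A: LabeledMatrix, S: FusedSimilarity, k: int = 10, decay: float = 0.9
) -> LabeledMatrix:
    """Fill all-zero rows of A from their k most similar rows.

    For an empty row p, the k nearest other rows j1..jk of S (descending
    S(p, j), ties broken by row id, self excluded) contribute with weight
    ``w_i = decay**(i-1) * S(p, j_i)``; the filled row is the w-weighted
    average of their association rows.  Rows with at least one positive pass
    through unchanged, as does an empty row whose weights all vanish.
    ``decay=1`` recovers plain similarity-weighted averaging.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < decay <= 1:
        raise ValueError("decay must be in (0, 1]")
    if S.ids != A.row_ids:
        raise AlignmentError("similarity matrix is not indexed by A's rows")
    m = A.shape[0]
    if k >= m:
        logger.warning("k=%d >= %d rows; clamping to %d", k, m, m - 1)
        k = m - 1
    out = A.values.astype(float).copy()
    for p in range(m):
        if out[p].any():
            continue
        others = [j for j in range(m) if j != p]
        # descending similarity, ties by id
        others.sort(key=lambda j: (-S.values[p, j], A.row_ids[j]))
        neighbors = others[:k]
        weights = np.array([decay**i * S.values[p, j] for i, j in enumerate(neighbors)])
        total = weights.sum()
        if total > 0:
            out[p] = weights @ A.values[neighbors, :] / total
    return LabeledMatrix(out, A.row_ids, A.col_ids)


def build_integrated(
    S: FusedSimilarity, A_block: LabeledMatrix, view: EntityView
) -> IntegratedMatrix:
    """Concatenate [S | A_block] for one view.

    For the drug view ``A_block`` is the (filled) m×n association matrix; for
    the disease view it is the disease-side filled matrix already transposed
    to n×m so that rows index diseases in both blocks.
    """
    if S.values.shape[0] != A_block.shape[0]:
        raise AlignmentError(
            f"similarity has {S.values.shape[0]} rows but association block has "
            f"{A_block.shape[0]}"
        )
    values = np.hstack([S.values, A_block.values])
    return IntegratedMatrix(values, sim_width=S.values.shape[0], view=view)


def build_laplacian(S: FusedSimilarity) -> GraphLaplacian:
    """Unnormalized graph Laplacian L = U − S, degrees = full row sums of S."""
    degrees = S.values.sum(axis=1)
    return GraphLaplacian(np.diag(degrees) - S.values)
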