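"""Per-cell count-rank frequency tables and pre-flight matrix diagnostics.

In sparse count data the nonzero values of a cell, ranked by how often they
occur, coincide with the integers 1, 2, 3, ... for the top ranks — zero is the
most common entry overall, 1 the most common nonzero, and so on.  Any
monotone per-cell transform (scaling, log) preserves this frequency ranking,
which is what makes the normalization invertible: the two most frequent
stored values of a cell are the images of counts 1 and 2.

This module builds those tables, merges near-duplicate values produced by
lossy storage, classifies a matrix as log-transformed or not from the
mean-variance relation of its genes, and quantifies how consistently value
equals rank across cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .matrix import GeneExpressionMatrix

__all__ = [
    "FrequencyTable",
    "rank_frequencies",
    "merge_near_duplicates",
    "detect_log_transform",
    "overdispersion_fraction",
    "count_rank_consistency",
    "IndeterminateMatrixError",
]


class IndeterminateMatrixError(ValueError):
    """The matrix carries too little signal to classify (e.g. all-constant)."""


def _rank_one(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Distinct values sorted by descending frequency, ties to smaller value."""
    vals, freqs = np.unique(values, return_counts=True)
    order = np.argsort(-freqs, kind="stable")  # np.unique sorts values ascending
    return vals[order], freqs[order]


@dataclass
class FrequencyTable:
    """Per-cell tables of distinct nonzero values ranked by frequency.

    ``values[i]`` and ``freqs[i]`` are aligned arrays for cell ``i``, ordered
    by descending frequency with ties broken toward the smaller value.  Cells
    without at least two distinct values cannot anchor the (count 1, count 2)
    ladder and are flagged unsolvable.
    """

    values: List[np.ndarray] = field(default_factory=list)
    freqs: List[np.ndarray] = field(default_factory=list)

    @classmethod
    def from_matrix(cls, matrix: GeneExpressionMatrix) -> "FrequencyTable":
        X = matrix.X
        values, freqs = [], []
        for i in range(X.shape[0]):
            v, f = _rank_one(X.data[X.indptr[i] : X.indptr[i + 1]])
            values.append(v)
            freqs.append(f)
        return cls(values, freqs)

    @property
    def n_cells(self) -> int:
        return len(self.values)

    def solvable(self) -> np.ndarray:
        """Cells with >= 2 distinct nonzero values."""
        return np.array([v.size >= 2 for v in self.values])

    def top_pair(self, i: int) -> Tuple[float, float]:
        """(N1, N2): the two most frequent values of cell ``i``."""
        v = self.values[i]
        if v.size < 2:
            raise ValueError(f"cell {i} has fewer than 2 distinct nonzero values")
        return float(v[0]), float(v[1])

    def top_pairs(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(N1, N2, solvable-mask) across all cells (NaN where unsolvable)."""
        n1 = np.full(self.n_cells, np.nan)
        n2 = np.full(self.n_cells, np.nan)
        mask = self.solvable()
        for i in np.flatnonzero(mask):
            n1[i], n2[i] = self.values[i][0], self.values[i][1]
        return n1, n2, mask

    def rank_value_pairs(self, i: int, k: int = 5) -> Tuple[np.ndarray, np.ndarray]:
        """(ranks 1..m, values) for the first ``m = min(k, K_i)`` ranks."""
        v = self.values[i][:k]
        return np.arange(1, v.size + 1, dtype=np.float64), v.astype(np.float64)


def rank_frequencies(cell_values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Rank the distinct nonzero values of one cell by descending frequency.

    Zeros are excluded; ties are broken toward the smaller value (under the
    negative-binomial model smaller counts are a priori more frequent).
    """
    cell_values = np.asarray(cell_values)
    cell_values = cell_values[cell_values != 0]
    if cell_values.size == 0:
        raise ValueError("cell has no nonzero values")
    return _rank_one(cell_values)


def _merge_at(values: np.ndarray, freqs: np.ndarray, decimals: int):
    """Pool values equal after rounding to ``decimals``; representative is the
    frequency-weighted mean.  Returns arrays re-ranked by frequency."""
    key = np.round(values, decimals)
    uniq, inverse = np.unique(key, return_inverse=True)
    f = np.bincount(inverse, weights=freqs)
    wsum = np.bincount(inverse, weights=freqs * values)
    rep = wsum / f
    order = np.lexsort((rep, -f))  # frequency desc, then smaller value
    return rep[order], f[order]


def merge_near_duplicates(
    table: FrequencyTable, start_decimals: int = 8, min_decimals: int = 3
) -> FrequencyTable:
    """Pool stored values that differ only by storage noise.

    Lossy storage can split one true normalized value into several nearby
    stored values, demoting its frequency rank.  Per cell, values rounding
    together at ``d`` decimals are merged (frequencies summed, representative
    = frequency-weighted mean), with ``d`` lowered from ``start_decimals``
    toward ``min_decimals`` until the top two values are *separated*: their
    gap exceeds one part in a thousand of their magnitude (storage noise is
    relative — half precision carries ~3 significant decimals — while a
    genuine count ladder is spaced by several percent at least), with
    ``10**-d`` as an absolute floor near zero.
    """
    if min_decimals > start_decimals:
        raise ValueError("min_decimals must be <= start_decimals")
    out = FrequencyTable()
    for values, freqs in zip(table.values, table.freqs):
        best_v, best_f = values, freqs
        for d in range(start_decimals, min_decimals - 1, -1):
            best_v, best_f = _merge_at(values, freqs, d)
            if best_v.size < 2:
                break
            gap = abs(best_v[1] - best_v[0])
            if gap > max(1e-3 * max(abs(best_v[0]), abs(best_v[1])), 10.0 ** (-d)):
                break
        out.values.append(best_v)
        out.freqs.append(best_f)
    return out


def overdispersion_fraction(
    matrix: GeneExpressionMatrix, gene_sample_size: int = 1000
) -> float:
    """Fraction of sampled genes whose variance exceeds their mean.

    Genes are sampled as the ``gene_sample_size`` most expressed, and the
    moments are taken over each gene's *stored (nonzero)* entries: raw counts
    are overdispersed there (negative binomial, nu = mu + phi*mu^2, so
    var/mean ~ 1 + phi*mu >> 1 for well-expressed genes) while log values are
    range-compressed far below their mean.  Dropout zeros are excluded on
    purpose — a gene whose entries are "0 or ~10" has a huge variance on any
    scale, which says nothing about the transform.  Genes with fewer than 5
    stored entries are uninformative either way and are left out.
    """
    X = matrix.X
    n = X.shape[0]
    if n < 2:
        raise IndeterminateMatrixError("need >= 2 cells to compare variance with mean")
    nnz = np.bincount(X.indices, minlength=X.shape[1]).astype(np.float64)
    s1 = np.bincount(X.indices, weights=X.data, minlength=X.shape[1])
    s2 = np.bincount(X.indices, weights=X.data**2, minlength=X.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / nnz
        var = (s2 / nnz - mean**2) * nnz / np.maximum(nnz - 1, 1)
    informative = (nnz >= 5) & (var > 0)
    if informative.sum() < 10:
        raise IndeterminateMatrixError("fewer than 10 informative genes")
    # prefer genes with stored mean >= 2: on the count side zero-truncation
    # is negligible there, and on the log side they are the best-expressed
    strong = informative & (mean >= 2)
    pool = strong if strong.sum() >= 10 else informative
    idx = np.argsort(np.where(pool, -mean, np.inf), kind="stable")
    idx = idx[: min(gene_sample_size, int(pool.sum()))]
    return float(np.mean(var[idx] > mean[idx]))


def detect_log_transform(
    matrix: GeneExpressionMatrix,
    gene_sample_size: int = 1000,
    threshold: float = 0.5,
) -> str:
    """Classify a matrix as ``'untransformed'`` or ``'transformed'``.

    Untransformed (count-like) data are overdispersed: the variance of a gene
    exceeds its mean.  When more than ``threshold`` of the sampled genes are
    overdispersed the matrix is called untransformed, else transformed.
    Matrices with negative stored values cannot be counts or scaled counts
    and are classified transformed outright.
    """
    if matrix.X.data.size and float(matrix.X.data.min()) < 0:
        return "transformed"
    frac = overdispersion_fraction(matrix, gene_sample_size)
    return "untransformed" if frac > threshold else "transformed"


def count_rank_consistency(
    matrix: GeneExpressionMatrix, k_max: int = 5, cumulative: bool = True
) -> np.ndarray:
    """Percentage of cells whose count-rank ladder is correct up to each k.

    For ``cumulative=True`` (the default), entry ``k-1`` is the percentage of
    cells whose j-th most frequent nonzero value equals j for *all* ranks
    ``j <= k`` — non-increasing in k by construction.  With
    ``cumulative=False`` each rank is assessed on its own (value at rank k
    equals k, regardless of earlier ranks).
    """
    if matrix.stage != "counts":
        raise ValueError("count_rank_consistency expects stage='counts'")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    table = FrequencyTable.from_matrix(matrix)
    hits = np.zeros(k_max)
    for v in table.values:
        m = min(v.size, k_max)
        ok = v[:m] == np.arange(1, m + 1)
        if cumulative:
            good = int(np.argmin(ok)) if not ok.all() else m
            hits[:good] += 1
        else:
            hits[:m][ok] += 1
    return 100.0 * hits / max(table.n_cells, 1)
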