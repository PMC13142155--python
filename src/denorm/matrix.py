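"""Sparse expression-matrix data model and the forward delta-normalization model.

The central object is :class:`GeneExpressionMatrix`, a thin wrapper around a
``scipy.sparse`` CSR matrix (cells as rows, genes as columns) that carries cell
and gene identifiers and a processing-stage tag.  The forward model implemented
here is the delta-method normalization used throughout droplet single-cell
workflows::

    N = log_b(C * L / T + p)

where ``C`` is the raw count, ``T`` the cell's library size (total counts),
``L`` the target sum, ``p`` the pseudo-count and ``b`` the log base.  With the
common choice ``p = 1`` the implicit zeros of the count matrix map exactly to
zero, so the sparsity pattern survives normalization; this is the structural
fact the whole package relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

__all__ = [
    "STAGES",
    "NO_LOG",
    "GeneExpressionMatrix",
    "DeltaParams",
    "delta_normalize",
    "round_to_counts",
    "round_half_away",
]

STAGES = ("counts", "scaled", "normalized", "denormalized")

#: Sentinel for "the data were scaled but never log-transformed".
NO_LOG = "no-log"


def _as_id_array(ids: Optional[Sequence[str]], n: int, prefix: str) -> np.ndarray:
    if ids is None:
        return np.array([f"{prefix}{i}" for i in range(n)], dtype=object)
    arr = np.asarray(ids, dtype=object)
    if arr.shape != (n,):
        raise ValueError(f"expected {n} {prefix}-ids, got {arr.shape}")
    return arr


@dataclass
class GeneExpressionMatrix:
    """Sparse cells x genes expression matrix with identifiers and a stage tag.

    Parameters
    ----------
    X
        Matrix of stored (nonzero) entries; converted to CSR with explicit
        zeros eliminated.
    cell_ids, gene_ids
        Ordered barcode / feature strings.  Generated (``cell0`` ...) when
        omitted.
    stage
        One of ``counts``, ``scaled``, ``normalized``, ``denormalized``.
    meta
        Free-form annotations (e.g. whether implicit zeros were left
        untransformed for a pseudo-count other than 1).
    """

    X: sp.csr_matrix
    cell_ids: Optional[Sequence[str]] = None
    gene_ids: Optional[Sequence[str]] = None
    stage: str = "counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        X = sp.csr_matrix(self.X)
        X.eliminate_zeros()
        self.X = X
        self.cell_ids = _as_id_array(self.cell_ids, X.shape[0], "cell")
        self.gene_ids = _as_id_array(self.gene_ids, X.shape[1], "gene")
        if self.stage == "counts":
            self._check_counts()

    def _check_counts(self) -> None:
        d = self.X.data
        if d.size and (np.any(d < 0) or np.any(d != np.floor(d))):
            raise ValueError("stage='counts' requires positive integer entries")

    # -- basic protocol -----------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.X.shape

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def nnz(self) -> int:
        return self.X.nnz

    def copy(self, stage: Optional[str] = None) -> "GeneExpressionMatrix":
        return GeneExpressionMatrix(
            self.X.copy(),
            self.cell_ids.copy(),
            self.gene_ids.copy(),
            stage or self.stage,
            dict(self.meta),
        )

    def row_data(self, i: int) -> np.ndarray:
        """Stored (nonzero) values of cell ``i``."""
        return self.X.data[self.X.indptr[i] : self.X.indptr[i + 1]]

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1), dtype=np.float64).ravel()

    def row_index_of_data(self) -> np.ndarray:
        """Row index for every element of ``X.data`` (CSR order)."""
        return np.repeat(np.arange(self.n_cells), np.diff(self.X.indptr))

    def with_data(self, data: np.ndarray, stage: str) -> "GeneExpressionMatrix":
        """New matrix with the same sparsity pattern but replaced values."""
        if data.shape != self.X.data.shape:
            raise ValueError("replacement data must match the stored-entry count")
        X = sp.csr_matrix(
            (np.asarray(data, dtype=np.float64), self.X.indices.copy(), self.X.indptr.copy()),
            shape=self.X.shape,
        )
        return GeneExpressionMatrix(X, self.cell_ids, self.gene_ids, stage, dict(self.meta))

    def subset_cells(self, index: np.ndarray) -> "GeneExpressionMatrix":
        return GeneExpressionMatrix(
            self.X[index], self.cell_ids[index], self.gene_ids, self.stage, dict(self.meta)
        )

    def subset_genes(self, index: np.ndarray) -> "GeneExpressionMatrix":
        return GeneExpressionMatrix(
            self.X[:, index], self.cell_ids, self.gene_ids[index], self.stage, dict(self.meta)
        )


@dataclass
class DeltaParams:
    """The delta-normalization triple (L, b, p) plus per-cell library sizes T.

    ``base`` may be the sentinel :data:`NO_LOG` for scaling without a log
    transform, in which case the pseudo-count must be 0.
    """

    target_sum: float = 1e4
    base: Union[float, str] = math.e
    pseudo_count: float = 1.0
    cell_totals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.target_sum <= 0:
            raise ValueError("target_sum must be positive")
        if self.base == NO_LOG:
            if self.pseudo_count != 0:
                raise ValueError("pseudo_count must be 0 when base is 'no-log'")
        elif not (isinstance(self.base, (int, float)) and self.base > 1):
            raise ValueError("base must be > 1 or the 'no-log' sentinel")
        if self.pseudo_count < 0:
            raise ValueError("pseudo_count must be >= 0")
        if self.cell_totals is not None:
            self.cell_totals = np.asarray(self.cell_totals, dtype=np.float64)
            if np.any(self.cell_totals <= 0):
                raise ValueError("cell_totals must be positive")

    @property
    def is_log(self) -> bool:
        return self.base != NO_LOG

    def to_dict(self) -> dict:
        return {
            "target_sum": self.target_sum,
            "base": self.base if self.base == NO_LOG else float(self.base),
            "pseudo_count": float(self.pseudo_count),
            "cell_totals": None
            if self.cell_totals is None
            else np.asarray(self.cell_totals).tolist(),
        }


def delta_normalize(
    matrix: GeneExpressionMatrix, params: DeltaParams
) -> GeneExpressionMatrix:
    """Apply the forward delta normalization ``N = log_b(C*L/T + p)``.

    Library sizes ``T`` come from ``params.cell_totals`` when given, otherwise
    from the row sums of ``matrix``.  Only stored entries are transformed;
    implicit zeros stay implicit.  When ``p == 1`` this is exact (``log_b(1) =
    0``); for any other pseudo-count the matrix is annotated with
    ``meta['zeros_untransformed'] = True`` since the zero image ``log_b(p)``
    cannot be represented sparsely.
    """
    if matrix.stage != "counts":
        raise ValueError(f"delta_normalize expects stage='counts', got {matrix.stage!r}")
    if np.any(matrix.X.data < 0):
        raise ValueError("negative stored values are not valid counts")
    T = params.cell_totals if params.cell_totals is not None else matrix.row_sums()
    T = np.asarray(T, dtype=np.float64)
    if T.shape != (matrix.n_cells,):
        raise ValueError("cell_totals length must equal the number of cells")
    zero = np.flatnonzero(T <= 0)
    if zero.size:
        raise ValueError(
            f"cells with zero library size cannot be normalized: rows {zero[:10].tolist()}"
        )
    rows = matrix.row_index_of_data()
    scaled = matrix.X.data.astype(np.float64) * (params.target_sum / T[rows])
    if params.is_log:
        data = np.log(scaled + params.pseudo_count) / math.log(params.base)
    else:
        data = scaled
    out = matrix.with_data(data, "normalized")
    if params.is_log and params.pseudo_count != 1:
        out.meta["zeros_untransformed"] = True
    return out


def round_half_away(values: np.ndarray) -> np.ndarray:
    """Round to the nearest integer with ties away from zero."""
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


def round_to_counts(matrix: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Integerize a denormalized matrix; entries rounding to <= 0 are dropped."""
    if matrix.stage != "denormalized":
        raise ValueError(
            f"round_to_counts expects stage='denormalized', got {matrix.stage!r}"
        )
    out = matrix.with_data(round_half_away(matrix.X.data), "denormalized")
    out.X.data[out.X.data <= 0] = 0.0
    out.X.eliminate_zeros()
    return GeneExpressionMatrix(out.X, out.cell_ids, out.gene_ids, "counts", dict(out.meta))
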