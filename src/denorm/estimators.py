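"""scikit-learn-style estimators for the forward and inverse delta model.

Two transformers that compose with sklearn pipelines and model selection:

* :class:`DeltaNormalizer` — the forward model ``N = log_b(C*L/T + p)``.
  Library sizes are a per-cell property, so the transform is computed from
  the rows of the matrix being transformed (like ``sklearn.preprocessing.
  Normalizer``, the estimator itself is stateless).
* :class:`Denormalizer` — the inverse.  ``fit`` infers the matrix-level
  parameters (log base and pseudo-count) from the count-rank frequency
  structure; ``transform`` inverts the log step with the fitted (b, p),
  re-estimates the per-cell scale factors of the given matrix (a per-cell
  statistic, like library size), multiplies each cell back to count scale
  and rounds to integers.

Both accept a ``scipy.sparse`` matrix, a dense array, or a
:class:`~denorm.matrix.GeneExpressionMatrix`, and return CSR matrices.
"""

from __future__ import annotations

import math
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .matrix import NO_LOG, DeltaParams, GeneExpressionMatrix, delta_normalize
from .pipeline import PipelineOptions, denormalize

__all__ = ["DeltaNormalizer", "Denormalizer"]

MatrixLike = Union[np.ndarray, sp.spmatrix, GeneExpressionMatrix]


def _to_gem(X: MatrixLike, stage: str) -> GeneExpressionMatrix:
    if isinstance(X, GeneExpressionMatrix):
        if X.stage != stage:
            return GeneExpressionMatrix(X.X, X.cell_ids, X.gene_ids, stage, dict(X.meta))
        return X
    return GeneExpressionMatrix(sp.csr_matrix(X), stage=stage)


class DeltaNormalizer(TransformerMixin, BaseEstimator):
    """Delta-method normalization ``N = log_b(C*L/T + p)`` of raw counts.

    Parameters
    ----------
    target_sum : float, default 1e4
        The value every cell sums to after library-size scaling (``L``).
    base : float or None, default e
        Log base ``b``; ``None`` scales without log-transforming (the
        pseudo-count must then be 0).
    pseudo_count : float, default 1.0
        Offset ``p`` added before the log; 1 gives the log1p convention
        under which implicit zeros map exactly to zero.

    Attributes
    ----------
    cell_totals_ : ndarray
        Library sizes of the matrix seen by ``fit``.
    n_features_in_ : int
    """

    def __init__(
        self,
        target_sum: float = 1e4,
        base: Optional[float] = math.e,
        pseudo_count: float = 1.0,
    ):
        self.target_sum = target_sum
        self.base = base
        self.pseudo_count = pseudo_count

    def _params(self) -> DeltaParams:
        return DeltaParams(
            target_sum=self.target_sum,
            base=NO_LOG if self.base is None else self.base,
            pseudo_count=self.pseudo_count,
        )

    def fit(self, X: MatrixLike, y=None) -> "DeltaNormalizer":
        self._params()  # validate hyper-parameters
        gem = _to_gem(X, "counts")
        self.cell_totals_ = gem.row_sums()
        self.n_features_in_ = gem.n_genes
        return self

    def transform(self, X: MatrixLike) -> sp.csr_matrix:
        check_is_fitted(self)
        gem = _to_gem(X, "counts")
        return delta_normalize(gem, self._params()).X

    def fit_transform(self, X: MatrixLike, y=None, **fit_params) -> sp.csr_matrix:
        return self.fit(X, y).transform(X)


class Denormalizer(TransformerMixin, BaseEstimator):
    """Invert delta-method normalization back to integer raw counts.

    ``fit`` learns the matrix-wide log base and pseudo-count from the
    count-rank frequency structure of a subset of cells; ``transform``
    applies the inverse transform and per-cell unscaling and returns the
    rounded integer count matrix as CSR.

    Parameters
    ----------
    cutoff : float, default 0.05
        Per-cell MAE (against nearest integers) below which a cell counts as
        successfully denormalized.
    subset_size : int, default 100
        Number of cells used to fit the shared (base, pseudo-count).
    method : {'closed-form', 'regression'}, default 'closed-form'
        Per-cell scale-factor estimator.
    base, pseudo_count, target_sum : optional overrides
        Force a parameter instead of inferring it (``base='no-log'`` for
        scaled-only data).
    random_state : int, default 0
        Seed for the subset draw.

    Attributes
    ----------
    base_ : float or 'no-log'
    pseudo_count_ : float
    fit_method_ : str
        How (b, p) were determined: empirical, optimized, forced or no-log.
    objective_ : float
        Final value of the top-pair least-squares objective.
    target_sum_ : float
        Inferred target sum (mode of detransformed cell sums).
    scale_factors_, cell_success_ : ndarray
        Per-cell factors and success flags for the matrix passed to ``fit``.
    success_rate_ : float
    report_ : DenormReport
        Full diagnostic report of the fit run.
    """

    def __init__(
        self,
        cutoff: float = 0.05,
        subset_size: int = 100,
        method: str = "closed-form",
        base: Optional[Union[float, str]] = None,
        pseudo_count: Optional[float] = None,
        target_sum: Optional[float] = None,
        merge_start_decimals: int = 8,
        merge_min_decimals: int = 3,
        random_state: int = 0,
    ):
        self.cutoff = cutoff
        self.subset_size = subset_size
        self.method = method
        self.base = base
        self.pseudo_count = pseudo_count
        self.target_sum = target_sum
        self.merge_start_decimals = merge_start_decimals
        self.merge_min_decimals = merge_min_decimals
        self.random_state = random_state

    def _options(self) -> PipelineOptions:
        return PipelineOptions(
            cutoff=self.cutoff,
            subset_size=self.subset_size,
            seed=self.random_state,
            method=self.method,
            base=self.base,
            pseudo_count=self.pseudo_count,
            target_sum=self.target_sum,
            merge_start_decimals=self.merge_start_decimals,
            merge_min_decimals=self.merge_min_decimals,
        )

    def _run(self, X: MatrixLike):
        gem = X if isinstance(X, GeneExpressionMatrix) else _to_gem_guess(X)
        return denormalize(gem, self._options())

    def fit(self, X: MatrixLike, y=None) -> "Denormalizer":
        counts, report = self._run(X)
        self._fitted_counts_ = counts
        self.report_ = report
        self.base_ = report.transform["base"]
        self.pseudo_count_ = report.transform["pseudo_count"]
        self.fit_method_ = report.transform["method"]
        self.objective_ = report.transform["objective"]
        self.target_sum_ = report.target_sum
        self.scale_factors_ = report.scales_.scales
        self.cell_success_ = report.scales_.success
        self.success_rate_ = report.success_rate
        self.n_features_in_ = counts.n_genes
        return self

    def transform(self, X: MatrixLike) -> sp.csr_matrix:
        check_is_fitted(self, "base_")
        gem = X if isinstance(X, GeneExpressionMatrix) else _to_gem_guess(X)
        opts = self._options()
        opts.base = self.base_
        opts.pseudo_count = self.pseudo_count_
        counts, _ = denormalize(gem, opts)
        return counts.X

    def fit_transform(self, X: MatrixLike, y=None, **fit_params) -> sp.csr_matrix:
        return self.fit(X, y)._fitted_counts_.X


def _to_gem_guess(X: MatrixLike) -> GeneExpressionMatrix:
    """Wrap an array with the stage guessed from integrality of its entries."""
    Xc = sp.csr_matrix(X)
    data = Xc.data
    integral = data.size == 0 or bool(
        np.all(data >= 0) and np.all(np.abs(data - np.rint(data)) <= 1e-9)
    )
    return GeneExpressionMatrix(Xc, stage="counts" if integral else "normalized")
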