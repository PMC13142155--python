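"""Stage 2 of denormalization: per-cell scale factors and the unscale step.

After the log step has been inverted, the stored value of a count ``c`` in
cell ``i`` is ``c / s_i`` with ``s_i = T_i / L`` (library size over target
sum).  Two estimators of ``s_i`` from the cell's frequency-ranked values:

* closed form from the top two values (images of counts 1 and 2):
  ``s = (c2 - c1) / (x2 - x1)`` — the pseudo-count, if still present,
  cancels in the difference;
* least squares over the top (at most) five rank-value pairs, minimizing
  ``sum_i (c_i/s + p - x_i)**2``.  The objective is quadratic in ``u = 1/s``,
  so the bounded minimizer is available analytically:
  ``u = sum c_i (x_i - p) / sum c_i**2`` (``u <= 0`` flags the cell
  unsolvable).

Multiplying each cell by its factor yields the denormalized matrix, whose
entries should sit on integers; the per-cell mean absolute error against the
nearest integers decides success (default cutoff 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .frequency import FrequencyTable, merge_near_duplicates
from .matrix import GeneExpressionMatrix, round_half_away

__all__ = [
    "CellScaleSet",
    "UnsolvableCellError",
    "scale_closed_form",
    "scale_regression",
    "estimate_scales",
    "unscale_matrix",
]

DEFAULT_CUTOFF = 0.05


class UnsolvableCellError(ValueError):
    """The cell's frequency table cannot anchor the count ladder."""


@dataclass
class CellScaleSet:
    """Per-cell scaling factors with fit status and success assessment."""

    scales: np.ndarray  # s_i; NaN where unsolvable
    solvable: np.ndarray  # bool
    method: str  # {closed-form, regression, identity}
    cell_ids: Optional[np.ndarray] = None
    mae: Optional[np.ndarray] = None  # per-cell MAE, NaN until assessed
    success: Optional[np.ndarray] = None
    residual: Optional[np.ndarray] = None  # regression residuals (if any)
    matrix_mae: float = float("nan")
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        n = len(self.scales)
        if self.mae is None:
            self.mae = np.full(n, np.nan)
        if self.success is None:
            self.success = np.zeros(n, dtype=bool)

    @property
    def n_cells(self) -> int:
        return len(self.scales)

    @property
    def n_success(self) -> int:
        return int(np.sum(self.success))

    def to_frame(self) -> pd.DataFrame:
        """Per-cell table (barcode, s, method, MAE, success) for export."""
        return pd.DataFrame(
            {
                "barcode": self.cell_ids
                if self.cell_ids is not None
                else np.arange(self.n_cells),
                "scale_factor": self.scales,
                "method": self.method,
                "solvable": self.solvable,
                "mae": self.mae,
                "success": self.success,
            }
        )

    def summary(self) -> dict:
        ok = self.scales[np.isfinite(self.scales)]
        return {
            "n_cells": self.n_cells,
            "n_solvable": int(np.sum(self.solvable)),
            "n_success": self.n_success,
            "method": self.method,
            "scale_min": float(ok.min()) if ok.size else None,
            "scale_median": float(np.median(ok)) if ok.size else None,
            "scale_max": float(ok.max()) if ok.size else None,
            "matrix_mae": None if np.isnan(self.matrix_mae) else float(self.matrix_mae),
        }


def scale_closed_form(x1: float, x2: float, c1: float = 1.0, c2: float = 2.0) -> float:
    """Closed-form scale factor ``s = (c2 - c1) / (x2 - x1)``."""
    if x2 <= x1:
        raise UnsolvableCellError("x2 must exceed x1 for the closed-form solution")
    return (c2 - c1) / (x2 - x1)


def scale_regression(
    ranks: np.ndarray, values: np.ndarray, pseudo_count: float = 0.0
) -> Tuple[float, float]:
    """Least-squares scale factor from rank-value pairs (at most 5 used).

    Minimizes ``sum (c_i/s + p - x_i)**2`` exactly via its quadratic form in
    ``1/s``.  Returns ``(s, residual)``; raises :class:`UnsolvableCellError`
    when fewer than two distinct values are given or the minimizer lands on
    a non-positive scale.
    """
    c = np.asarray(ranks, dtype=np.float64)[:5]
    x = np.asarray(values, dtype=np.float64)[:5]
    if c.size < 2 or np.unique(x).size < 2:
        raise UnsolvableCellError("need >= 2 pairs with distinct values")
    u = float(np.sum(c * (x - pseudo_count)) / np.sum(c**2))
    if u <= 0:
        raise UnsolvableCellError("regression minimizer implies a non-positive scale")
    s = 1.0 / u
    residual = float(np.sum((c * u + pseudo_count - x) ** 2))
    return s, residual


def estimate_scales(
    matrix: GeneExpressionMatrix,
    method: str = "closed-form",
    table: Optional[FrequencyTable] = None,
    pseudo_count: float = 0.0,
    merge: bool = True,
    merge_start_decimals: int = 8,
    merge_min_decimals: int = 3,
) -> CellScaleSet:
    """One scale factor per solvable cell of a scaled matrix.

    ``method='closed-form'`` (default — fast and robust) uses the top two
    merged values; ``'regression'`` the top five rank-value pairs.  Cells with
    fewer than two distinct merged values are flagged unsolvable, never
    dropped: they stay in the denominator of the success rate.
    """
    if matrix.stage != "scaled":
        raise ValueError("estimate_scales expects stage='scaled'")
    if method not in ("closed-form", "regression"):
        raise ValueError(f"unknown method {method!r}")
    if table is None:
        table = FrequencyTable.from_matrix(matrix)
        if merge:
            table = merge_near_duplicates(table, merge_start_decimals, merge_min_decimals)
    n = table.n_cells
    scales = np.full(n, np.nan)
    solvable = np.zeros(n, dtype=bool)
    residual = np.full(n, np.nan)
    for i in range(n):
        if table.values[i].size < 2:
            continue
        try:
            if method == "closed-form":
                x1, x2 = table.top_pair(i)
                scales[i] = scale_closed_form(x1, x2)
            else:
                c, x = table.rank_value_pairs(i, k=5)
                scales[i], residual[i] = scale_regression(c, x, pseudo_count)
            solvable[i] = True
        except UnsolvableCellError:
            continue
    return CellScaleSet(
        scales=scales,
        solvable=solvable,
        method=method,
        cell_ids=np.asarray(matrix.cell_ids),
        residual=residual,
    )


def unscale_matrix(
    matrix: GeneExpressionMatrix,
    scales: CellScaleSet,
    cutoff: float = DEFAULT_CUTOFF,
    refine: bool = True,
) -> Tuple[GeneExpressionMatrix, CellScaleSet]:
    """Multiply each cell by its scale factor and assess per-cell success.

    With ``refine=True`` (default) each solvable cell's factor gets one
    integer-anchored least-squares polish: once the ladder estimate has
    rounded the cell onto integers, ``s <- sum(x * round(x*s)) / sum(x**2)``
    re-fits the factor against those integers using *every* stored entry.
    On exact data this is a fixed point (the estimate is unchanged); on
    precision-degraded data it averages the storage noise over the whole
    cell instead of leaving it on the two anchor values.  A refinement that
    degenerates (non-positive or non-finite) is discarded.

    Unsolvable cells keep their scaled values and ``success=False``.  The
    per-cell MAE is the mean ``|y - round(y)|`` over stored entries (implicit
    zeros are exact by construction); the matrix-level MAE pools the stored
    entries of solvable cells.
    """
    if matrix.stage != "scaled":
        raise ValueError("unscale_matrix expects stage='scaled'")
    if scales.n_cells != matrix.n_cells:
        raise ValueError("scales are not aligned to the matrix cells")
    rows = matrix.row_index_of_data()
    factor = np.where(np.isfinite(scales.scales), scales.scales, 1.0)
    x = matrix.X.data.astype(np.float64)
    data = x * factor[rows]
    if refine:
        anchored = round_half_away(data)
        num = np.bincount(rows, weights=x * anchored, minlength=matrix.n_cells)
        den = np.bincount(rows, weights=x * x, minlength=matrix.n_cells)
        with np.errstate(invalid="ignore", divide="ignore"):
            s_new = num / den
        good = scales.solvable & np.isfinite(s_new) & (s_new > 0)
        factor = np.where(good, s_new, factor)
        scales.scales = np.where(good, s_new, scales.scales)
        data = x * factor[rows]
    out = matrix.with_data(data, "denormalized")

    abs_err = np.abs(data - round_half_away(data))
    nnz_per_cell = np.diff(matrix.X.indptr)
    sums = np.bincount(rows, weights=abs_err, minlength=matrix.n_cells)
    mae = np.divide(
        sums, nnz_per_cell, out=np.full(matrix.n_cells, np.nan), where=nnz_per_cell > 0
    )
    mae[~scales.solvable] = np.nan
    # a successful cell must keep at least one nonzero recovered count — a
    # scale factor that collapses every value below 0.5 gives a deceptively
    # small MAE while recovering nothing
    kept = np.bincount(rows, weights=(round_half_away(data) >= 0.5), minlength=matrix.n_cells)
    success = scales.solvable & (mae < cutoff) & (nnz_per_cell > 0) & (kept > 0)
    pooled = abs_err[scales.solvable[rows]]
    scales.mae = mae
    scales.success = success
    scales.cutoff = cutoff
    scales.matrix_mae = float(np.mean(pooled)) if pooled.size else float("nan")
    return out, scales
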