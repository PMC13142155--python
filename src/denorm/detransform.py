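"""Stage 1 of denormalization: infer and invert the log transform.

The whole matrix shares one log base ``b`` and pseudo-count ``p``.  Writing
``s_i = T_i / L`` for the per-cell scale factor, the images of counts 1 and 2
in cell ``i`` satisfy::

    1/s_i + p = b**N1_i        2/s_i + p = b**N2_i

where (N1, N2) are the two most frequent stored values of the cell.
Eliminating ``s_i`` gives the identity ``p = 2*b**N1 - b**N2``, which holds
for every cell simultaneously only at the true (b, p).  The search first
tries the empirical candidates used by standard workflows (bases 2, e, 10;
pseudo-counts 1, 0, 0.1, 0.01), validating each by a trial unscale of a
subset of cells; if none passes, (b, p) is fitted by bounded L-BFGS-B on the
least-squares objective  sum_i (p - 2*b**N1_i + b**N2_i)**2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .frequency import FrequencyTable
from .matrix import NO_LOG, GeneExpressionMatrix, round_half_away

__all__ = [
    "TransformFit",
    "ValidationResult",
    "EMPIRICAL_BASES",
    "EMPIRICAL_PSEUDO_COUNTS",
    "empirical_search",
    "trial_unscale_maes",
    "fit_base_pseudocount",
    "apply_detransform",
    "validate_scaled",
    "equation_objective",
]

EMPIRICAL_BASES: Tuple[float, ...] = (2.0, math.e, 10.0)
#: 1 first: the log1p convention is the overwhelmingly common case.
EMPIRICAL_PSEUDO_COUNTS: Tuple[float, ...] = (1.0, 0.0, 0.1, 0.01)

_MAX_EXP = 500.0  # exponent clip: keeps the objective finite at extreme (b, p)


@dataclass
class TransformFit:
    """A fitted (base, pseudo-count) pair with its provenance and quality."""

    base: float | str
    pseudo_count: float
    method: str  # {empirical, optimized, forced, no-log}
    objective: float = 0.0
    subset_cell_ids: Optional[Sequence[str]] = None
    status: str = "accepted"  # {accepted, rejected}
    p_variance: float = float("nan")
    detail: dict = field(default_factory=dict)

    @property
    def is_log(self) -> bool:
        return self.base != NO_LOG

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    def to_dict(self) -> dict:
        return {
            "base": self.base if self.base == NO_LOG else float(self.base),
            "pseudo_count": float(self.pseudo_count),
            "method": self.method,
            "objective": float(self.objective),
            "status": self.status,
            "p_variance": None if math.isnan(self.p_variance) else float(self.p_variance),
            "subset_cell_ids": None
            if self.subset_cell_ids is None
            else list(map(str, self.subset_cell_ids)),
        }


@dataclass
class ValidationResult:
    passed: bool
    path: str  # {sum-check, probe-mse, probe-mae, failed}
    detail: dict = field(default_factory=dict)

    def __bool__(self) -> bool:
        return self.passed


def _powb(base: float, exponent: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(np.asarray(exponent, dtype=np.float64) * math.log(base), None, _MAX_EXP))


def equation_objective(base: float, pseudo_count: float, n1: np.ndarray, n2: np.ndarray) -> float:
    """Mean squared residual of the per-cell identity p = 2*b**N1 - b**N2."""
    r = pseudo_count - 2.0 * _powb(base, n1) + _powb(base, n2)
    return float(np.mean(r**2))


def trial_unscale_maes(
    matrix: GeneExpressionMatrix,
    table: FrequencyTable,
    base: float | str,
    pseudo_count: float,
) -> np.ndarray:
    """Per-cell MAE to nearest integers after detransforming with (b, p) and
    unscaling each cell by the closed-form factor from its top-2 values.

    NaN for cells that cannot anchor the ladder (unsolvable or inverted).
    """
    maes = np.full(table.n_cells, np.nan)
    X = matrix.X
    log = base != NO_LOG
    for i in range(table.n_cells):
        v = table.values[i]
        if v.size < 2:
            continue
        if log:
            x1, x2 = _powb(base, v[:2]) - pseudo_count
        else:
            x1, x2 = float(v[0]), float(v[1])
        if not np.isfinite(x1) or not np.isfinite(x2) or x2 <= x1:
            continue
        s = 1.0 / (x2 - x1)
        if x1 * s <= 0.5:
            # the most frequent value must recover to a count >= 1; a scale
            # that collapses it to zero trivializes the MAE and is a failure
            maes[i] = np.inf
            continue
        row = X.data[X.indptr[i] : X.indptr[i + 1]].astype(np.float64)
        y = ((_powb(base, row) - pseudo_count) if log else row) * s
        maes[i] = float(np.mean(np.abs(y - round_half_away(y))))
    return maes


def empirical_search(
    subset: GeneExpressionMatrix,
    table: Optional[FrequencyTable] = None,
    candidates_b: Sequence[float] = EMPIRICAL_BASES,
    candidates_p: Sequence[float] = EMPIRICAL_PSEUDO_COUNTS,
    cutoff: float = 0.05,
    validation_fraction: float = 0.5,
) -> Optional[TransformFit]:
    """Try the empirical (base, pseudo-count) candidates on a subset of cells.

    A candidate passes when at least ``validation_fraction`` of the solvable
    subset cells survive a trial unscale (per-cell MAE to nearest integers
    below ``cutoff``).  Among passing candidates the one with the smallest
    median MAE wins — a wrong-by-a-small-offset pseudo-count (e.g. p = 0
    against true p = 0.1) can sneak below the cutoff on shallow cells, but
    its MAE is orders of magnitude above the true candidate's.  Returns
    ``None`` when every candidate fails — a valid outcome that hands over to
    :func:`fit_base_pseudocount`.
    """
    if table is None:
        table = FrequencyTable.from_matrix(subset)
    n1, n2, mask = table.top_pairs()
    if not mask.any():
        return None
    best = None
    for p in candidates_p:
        for b in candidates_b:
            maes = trial_unscale_maes(subset, table, b, p)
            ok = maes[np.isfinite(maes)]
            if ok.size == 0 or np.mean(ok < cutoff) < validation_fraction:
                continue
            med = float(np.median(ok))
            if best is None or med < best[0]:
                best = (med, b, p)
    if best is None:
        return None
    med, b, p = best
    return TransformFit(
        base=b,
        pseudo_count=p,
        method="empirical",
        objective=equation_objective(b, p, n1[mask], n2[mask]),
        subset_cell_ids=list(subset.cell_ids),
        p_variance=_solved_p_variance(b, n1[mask], n2[mask]),
        detail={"subset_mae_median": med},
    )


def _profiled_p(base: float, n1: np.ndarray, n2: np.ndarray, p_lo: float, p_hi: float) -> float:
    """Optimal pseudo-count for a fixed base (the objective is quadratic in p)."""
    return float(np.clip(np.mean(2.0 * _powb(base, n1) - _powb(base, n2)), p_lo, p_hi))


def _solved_p_variance(base: float, n1: np.ndarray, n2: np.ndarray) -> float:
    """Variance across cells of the per-cell solved pseudo-count
    2*b**N1 - b**N2 — small when the pseudo-count really is shared."""
    return float(np.var(2.0 * _powb(base, n1) - _powb(base, n2)))


def fit_base_pseudocount(
    n1: np.ndarray,
    n2: np.ndarray,
    bounds: Tuple[Tuple[float, float], Tuple[float, float]] = ((1.000001, 100.0), (0.0, 10.0)),
    tol: float = 1e-5,
    subset_cell_ids: Optional[Sequence[str]] = None,
    validate=None,
) -> TransformFit:
    """Fit (b, p) by bounded L-BFGS-B on the top-pair least-squares objective.

    Multi-started from the empirical bases and the best points of a profiled
    base grid.  The fit is accepted when the mean per-cell squared residual
    is at most ``tol``; a rejected fit is returned (not raised) so the caller
    can report the trail.

    ``validate``, when given, is a callable ``(b, p) -> bool`` used to pick
    among near-tied local minima: candidates are tried in order of objective
    and the first that validates wins.  This matters because the objective
    degenerates as ``b -> 1`` and cannot by itself distinguish the true
    basin from the boundary plateau on noisy data.
    """
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    keep = np.isfinite(n1) & np.isfinite(n2) & (n1 != n2)
    if keep.sum() == 0:
        raise ValueError("all cells have N1 == N2; the (b, p) system is unsolvable")
    if keep.sum() < 10:
        raise ValueError("need >= 10 cells with distinct (N1, N2) pairs")
    n1, n2 = n1[keep], n2[keep]

    def fun(theta: np.ndarray) -> float:
        return equation_objective(theta[0], theta[1], n1, n2)

    # Profile out p (optimal p for fixed b is the mean of 2*b**N1 - b**N2,
    # clipped to its bounds) to seed the 2-D refinement.  Note the objective
    # degenerates as b -> 1 (every b**N -> 1, so p = 1 fits anything); the
    # caller must validate an optimized fit against the data, the objective
    # alone cannot reject a non-delta matrix.
    (b_lo, b_hi), (p_lo, p_hi) = bounds
    bgrid = np.geomspace(max(b_lo, 1.05), b_hi, 80)
    starts = [(2.0, 1.0), (math.e, 1.0), (10.0, 1.0), (math.e, 0.0)]
    for b0 in bgrid[
        np.argsort([fun([b0, _profiled_p(b0, n1, n2, p_lo, p_hi)]) for b0 in bgrid])[:3]
    ]:
        starts.append((float(b0), _profiled_p(float(b0), n1, n2, p_lo, p_hi)))
    candidates = []
    for b0, p0 in starts:
        res = minimize(
            fun,
            x0=[b0, p0],
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-18, "gtol": 1e-14, "maxiter": 500},
        )
        candidates.append(res)
    candidates.sort(key=lambda r: r.fun)
    best = candidates[0]
    validated = None
    if validate is not None:
        for res in candidates:
            if res.fun <= tol and validate(float(res.x[0]), float(res.x[1])):
                validated = res
                break
        if validated is not None:
            best = validated
    b, p = float(best.x[0]), float(best.x[1])
    obj = float(best.fun)
    status = "accepted" if obj <= tol and (validate is None or validated is not None) else "rejected"
    return TransformFit(
        base=b,
        pseudo_count=p,
        method="optimized",
        objective=obj,
        subset_cell_ids=subset_cell_ids,
        status=status,
        p_variance=_solved_p_variance(b, n1, n2),
        detail={"converged": bool(best.success), "n_pairs": int(n1.size)},
    )


def apply_detransform(matrix: GeneExpressionMatrix, fit: TransformFit) -> GeneExpressionMatrix:
    """Invert the log step: every stored entry N becomes ``b**N - p``.

    Implicit zeros are untouched.  For the ``no-log`` method this is the
    identity map.  Cells producing values below ``-1e-9`` are recorded in
    ``meta['sign_violations']`` (count per offending cell) — a warning sign
    that the transform model does not match the data.
    """
    if matrix.stage != "normalized":
        raise ValueError("apply_detransform expects stage='normalized'")
    if not fit.accepted:
        raise ValueError("refusing to apply a rejected transform fit")
    if not fit.is_log:
        out = matrix.with_data(matrix.X.data.astype(np.float64), "scaled")
        return out
    data = _powb(fit.base, matrix.X.data) - fit.pseudo_count
    out = matrix.with_data(data, "scaled")
    neg = data < -1e-9
    if neg.any():
        rows = out.row_index_of_data()[neg]
        uniq, cnt = np.unique(rows, return_counts=True)
        out.meta["sign_violations"] = {int(r): int(c) for r, c in zip(uniq, cnt)}
    return out


def validate_scaled(
    matrix: GeneExpressionMatrix,
    sum_tol: float = 0.5,
    mse_tol: float = 1e-5,
    sum_fraction: float = 0.9,
    cutoff: float = 0.05,
    table: Optional[FrequencyTable] = None,
    n_probe: int = 20,
) -> ValidationResult:
    """Decide whether a detransformed matrix looks like scaled counts.

    Three acceptance paths, tried in order:

    1. *sum check*: after detransforming, every cell should sum to (nearly)
       the same target sum; passes when ``|row_sum - mean| < sum_tol`` for at
       least ``sum_fraction`` of the cells.
    2. *probe MSE*: gene filtering breaks the sum, so probe cells are trial
       unscaled; passes when the median per-value squared error against
       nearest integers is at most ``mse_tol``.
    3. *probe MAE*: lossy storage inflates the MSE while the data remain
       recoverable; passes when the median probe-cell MAE is below the
       success ``cutoff``.
    """
    if matrix.stage != "scaled":
        raise ValueError("validate_scaled expects stage='scaled'")
    sums = matrix.row_sums()
    mean = float(np.mean(sums))
    frac = float(np.mean(np.abs(sums - mean) < sum_tol))
    detail = {"mean_sum": mean, "fraction_within_sum_tol": frac}
    if frac >= sum_fraction:
        return ValidationResult(True, "sum-check", detail)

    if table is None:
        table = FrequencyTable.from_matrix(matrix)
    X = matrix.X
    mses, maes = [], []
    for i in range(table.n_cells):
        if len(mses) >= n_probe:
            break
        v = table.values[i]
        if v.size < 2 or v[1] <= v[0]:
            continue
        s = 1.0 / (v[1] - v[0])
        y = X.data[X.indptr[i] : X.indptr[i + 1]].astype(np.float64) * s
        err = y - round_half_away(y)
        mses.append(float(np.mean(err**2)))
        maes.append(float(np.mean(np.abs(err))))
    if not mses:
        return ValidationResult(False, "failed", {**detail, "reason": "no solvable probe cells"})
    detail["probe_mse_median"] = float(np.median(mses))
    detail["probe_mae_median"] = float(np.median(maes))
    if detail["probe_mse_median"] <= mse_tol:
        return ValidationResult(True, "probe-mse", detail)
    if detail["probe_mae_median"] < cutoff:
        return ValidationResult(True, "probe-mae", detail)
    return ValidationResult(False, "failed", detail)
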