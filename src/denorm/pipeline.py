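"""End-to-end denormalization: detect -> detransform -> unscale -> evaluate.

`denormalize` orchestrates the whole inversion on one matrix;
`denormalize_by_group` runs it independently per sample (each group gets its
own base, pseudo-count, target sum and per-cell factors) and recombines the
result in input cell order.  Failure is loud: when no stage combination
validates, :class:`DenormalizationFailure` is raised carrying the diagnostic
trail, and no matrix is emitted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from . import detransform as dt
from .evaluate import DenormReport, recovery_errors, rounding_errors, success_rate
from .frequency import (
    FrequencyTable,
    IndeterminateMatrixError,
    detect_log_transform,
    merge_near_duplicates,
)
from .matrix import (
    NO_LOG,
    DeltaParams,
    GeneExpressionMatrix,
    round_half_away,
    round_to_counts,
)
from .unscale import CellScaleSet, estimate_scales, unscale_matrix

__all__ = ["PipelineOptions", "DenormalizationFailure", "denormalize", "denormalize_by_group"]

logger = logging.getLogger("denorm")


class DenormalizationFailure(RuntimeError):
    """The matrix could not be denormalized; carries the diagnostic trail."""

    def __init__(self, message: str, trail: Optional[list] = None):
        super().__init__(message)
        self.trail = trail or []


@dataclass
class PipelineOptions:
    """Tunable knobs of the denormalization pipeline.

    ``cutoff`` is the per-cell MAE success threshold; ``subset_size`` the
    number of cells used to fit the shared (base, pseudo-count); ``base``,
    ``pseudo_count`` and ``target_sum`` force the corresponding parameter
    instead of inferring it.
    """

    cutoff: float = 0.05
    subset_size: int = 100
    seed: int = 0
    method: str = "closed-form"  # scale estimation: closed-form | regression
    base: Optional[float | str] = None
    pseudo_count: Optional[float] = None
    target_sum: Optional[float] = None
    merge_start_decimals: int = 8
    merge_min_decimals: int = 3
    validation_fraction: float = 0.5
    refine_scales: bool = True
    sum_tol: float = 0.5
    mse_tol: float = 1e-5
    fit_tol: float = 1e-5
    compute_recovery: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.subset_size < 10:
            raise ValueError("subset_size must be >= 10")


def _is_integral(data: np.ndarray, tol: float = 1e-9) -> bool:
    return bool(data.size == 0 or np.all(np.abs(data - round_half_away(data)) <= tol))


def _subset_indices(
    table: FrequencyTable, subset_size: int, seed: int
) -> np.ndarray:
    solvable = np.flatnonzero(table.solvable())
    if solvable.size == 0:
        return solvable
    rng = np.random.default_rng(seed)
    k = min(subset_size, solvable.size)
    return np.sort(rng.choice(solvable, size=k, replace=False))


def _table_subset(table: FrequencyTable, idx: np.ndarray) -> FrequencyTable:
    return FrequencyTable([table.values[i] for i in idx], [table.freqs[i] for i in idx])


def _detransform_table(table: FrequencyTable, fit: dt.TransformFit) -> FrequencyTable:
    """Map a frequency table through b**v - p (monotone: ranking survives)."""
    if not fit.is_log:
        return table
    lb = math.log(fit.base)
    vals = [np.exp(np.clip(v * lb, None, 500.0)) - fit.pseudo_count for v in table.values]
    return FrequencyTable(vals, [f.copy() for f in table.freqs])


def _infer_target_sum(scaled: GeneExpressionMatrix) -> Optional[float]:
    """Mode of the rounded row sums of the scaled matrix (reported, not used
    in the inversion itself)."""
    sums = round_half_away(scaled.row_sums())
    if sums.size == 0:
        return None
    vals, cnt = np.unique(sums, return_counts=True)
    return float(vals[np.argmax(cnt)])


def denormalize(
    matrix: GeneExpressionMatrix,
    options: Optional[PipelineOptions] = None,
    **kwargs,
) -> Tuple[GeneExpressionMatrix, DenormReport]:
    """Recover the integer count matrix behind a delta-normalized one.

    Returns ``(counts, report)``.  The report carries the fitted transform,
    per-cell scale summary, error summaries and verdict, plus (as non-field
    attributes) ``denormalized_`` (pre-rounding values) and ``scales_`` (the
    full per-cell table).  Raises :class:`DenormalizationFailure` when the
    data do not follow the delta model.
    """
    if options is None:
        options = PipelineOptions(**kwargs)
    elif kwargs:
        raise TypeError("pass either options or keyword arguments, not both")
    trail: list = []

    def stage(name: str, **info) -> None:
        logger.info("%s: %s", name, info)
        trail.append({"stage": name, **info})

    # ---- classify ---------------------------------------------------------
    if matrix.stage in ("counts", "scaled"):
        verdict = "untransformed"
    elif options.base is not None:
        verdict = "untransformed" if options.base == NO_LOG else "forced"
    else:
        try:
            verdict = detect_log_transform(matrix)
        except IndeterminateMatrixError as exc:
            raise DenormalizationFailure(f"indeterminate matrix: {exc}", trail) from exc
    stage("detect_log_transform", verdict=verdict)

    table = FrequencyTable.from_matrix(matrix)
    if matrix.stage != "counts":
        table = merge_near_duplicates(
            table, options.merge_start_decimals, options.merge_min_decimals
        )

    # ---- detransform ------------------------------------------------------
    if matrix.stage in ("counts", "scaled"):
        fit = dt.TransformFit(base=NO_LOG, pseudo_count=0.0, method="no-log")
        scaled = GeneExpressionMatrix(
            matrix.X.astype(np.float64), matrix.cell_ids, matrix.gene_ids, "scaled", dict(matrix.meta)
        )
        stage("detransform", method="no-log")
    else:
        normalized = matrix
        idx = _subset_indices(table, options.subset_size, options.seed)
        if idx.size < 10:
            raise DenormalizationFailure(
                "fewer than 10 solvable cells to fit the transform", trail
            )
        sub = normalized.subset_cells(idx)
        sub_table = _table_subset(table, idx)

        def _trial_fraction(b, p) -> float:
            maes = dt.trial_unscale_maes(sub, sub_table, b, p)
            ok = maes[np.isfinite(maes)]
            return float(np.mean(ok < options.cutoff)) if ok.size else 0.0

        fit = None
        if options.base is not None:
            fit = dt.TransformFit(
                base=options.base,
                pseudo_count=options.pseudo_count if options.pseudo_count is not None else 1.0,
                method="forced",
            )
            stage("transform_fit", method="forced", base=fit.base, pseudo_count=fit.pseudo_count)
        else:
            # The detection verdict orders the attempts; every fit must still
            # validate by trial unscale, so a borderline verdict cannot send
            # a recoverable matrix down a dead end.
            if verdict == "untransformed" and _trial_fraction(NO_LOG, 0.0) >= options.validation_fraction:
                fit = dt.TransformFit(base=NO_LOG, pseudo_count=0.0, method="no-log")
                stage("no_log_trial", accepted=True)
            if fit is None:
                fit = dt.empirical_search(
                    sub,
                    sub_table,
                    cutoff=options.cutoff,
                    validation_fraction=options.validation_fraction,
                )
                if fit is not None:
                    stage(
                        "empirical_search",
                        base=fit.base,
                        pseudo_count=fit.pseudo_count,
                        objective=fit.objective,
                    )
                else:
                    stage("empirical_search", result="no candidate passed")
            if fit is None and verdict != "untransformed":
                if _trial_fraction(NO_LOG, 0.0) >= options.validation_fraction:
                    fit = dt.TransformFit(base=NO_LOG, pseudo_count=0.0, method="no-log")
                    stage("no_log_trial", accepted=True)
            if fit is None:
                n1, n2, mask = sub_table.top_pairs()

                def _validator(b: float, p: float) -> bool:
                    return _trial_fraction(b, p) >= options.validation_fraction

                try:
                    fit = dt.fit_base_pseudocount(
                        n1[mask],
                        n2[mask],
                        tol=options.fit_tol,
                        subset_cell_ids=list(sub.cell_ids),
                        validate=_validator,
                    )
                except ValueError as exc:
                    raise DenormalizationFailure(str(exc), trail) from exc
                stage(
                    "fit_base_pseudocount",
                    base=fit.base,
                    pseudo_count=fit.pseudo_count,
                    objective=fit.objective,
                    status=fit.status,
                )
                if not fit.accepted:
                    raise DenormalizationFailure(
                        f"no transform fit validated (final objective {fit.objective:.3g}); "
                        "the matrix does not follow the delta model",
                        trail,
                    )
        scaled = dt.apply_detransform(normalized, fit)
        table = _detransform_table(table, fit)
        stage(
            "detransform",
            method=fit.method,
            sign_violations=len(scaled.meta.get("sign_violations", {})),
        )
        validation = dt.validate_scaled(
            scaled,
            sum_tol=options.sum_tol,
            mse_tol=options.mse_tol,
            cutoff=options.cutoff,
            table=table,
        )
        stage("validate_scaled", passed=validation.passed, path=validation.path, **validation.detail)
        if not validation.passed:
            raise DenormalizationFailure(
                "detransformed matrix failed validation (not delta-normalized data?)", trail
            )

    # ---- unscale ----------------------------------------------------------
    if matrix.stage == "counts" or (not fit.is_log and _is_integral(scaled.X.data)):
        # already counts: identity path
        n = scaled.n_cells
        scales = CellScaleSet(
            scales=np.ones(n),
            solvable=np.ones(n, dtype=bool),
            method="identity",
            cell_ids=np.asarray(scaled.cell_ids),
        )
        denormalized, scales = unscale_matrix(
            scaled, scales, cutoff=options.cutoff, refine=options.refine_scales
        )
        stage("unscale", method="identity")
    else:
        scales = estimate_scales(
            scaled, method=options.method, table=table, pseudo_count=0.0
        )
        denormalized, scales = unscale_matrix(
            scaled, scales, cutoff=options.cutoff, refine=options.refine_scales
        )
        stage(
            "unscale",
            method=options.method,
            n_solvable=int(np.sum(scales.solvable)),
            matrix_mae=scales.matrix_mae,
        )
    if not np.isfinite(scales.matrix_mae) or scales.matrix_mae >= options.cutoff:
        raise DenormalizationFailure(
            f"matrix MAE {scales.matrix_mae:.4g} is not below the cutoff {options.cutoff}", trail
        )

    # ---- evaluate ---------------------------------------------------------
    counts = round_to_counts(denormalized)
    _, rounding = rounding_errors(denormalized)
    rate = success_rate(scales)
    target_sum = options.target_sum or _infer_target_sum(scaled)
    verdict_final = "success" if rate == 1.0 else "partial"
    recovery = None
    if options.compute_recovery and matrix.stage == "normalized" and fit.is_log:
        params = DeltaParams(
            target_sum=target_sum or 1e4, base=fit.base, pseudo_count=fit.pseudo_count
        )
        try:
            _, recovery = recovery_errors(matrix, denormalized, params)
        except ValueError:
            recovery = None
    stage("evaluate", success_rate=rate, verdict=verdict_final, **rounding)

    report = DenormReport(
        transform=fit.to_dict(),
        target_sum=target_sum,
        scale_summary=scales.summary(),
        rounding=rounding,
        success_rate=rate,
        verdict=verdict_final,
        recovery=recovery,
        stages=trail,
    )
    report.denormalized_ = denormalized
    report.scales_ = scales
    return counts, report


def denormalize_by_group(
    matrix: GeneExpressionMatrix,
    groups: Sequence,
    options: Optional[PipelineOptions] = None,
    share_base: bool = False,
    **kwargs,
) -> Tuple[GeneExpressionMatrix, dict]:
    """Denormalize each sample independently and recombine in input order.

    ``groups`` assigns every cell a label; each group gets its own transform
    fit, target sum and per-cell factors (with ``share_base=True`` the (b, p)
    fitted on the first successful group is forced on the rest).  A group
    that fails is reported as failed — its cells are returned as all-zero
    rows — while the other groups proceed.  Raises when every group fails.
    """
    if options is None:
        options = PipelineOptions(**kwargs)
    elif kwargs:
        raise TypeError("pass either options or keyword arguments, not both")
    groups = np.asarray(groups)
    if groups.shape != (matrix.n_cells,):
        raise ValueError("every cell needs a group label")
    labels = list(dict.fromkeys(groups.tolist()))  # first-appearance order

    import scipy.sparse as sp

    blocks, order, reports = [], [], {}
    shared: Optional[dt.TransformFit] = None
    for label in labels:
        idx = np.flatnonzero(groups == label)
        sub = matrix.subset_cells(idx)
        opts = options
        if share_base and shared is not None:
            opts = replace(options, base=shared.base, pseudo_count=shared.pseudo_count)
        try:
            counts, report = denormalize(sub, opts)
            if share_base and shared is None:
                tr = report.transform
                shared = dt.TransformFit(tr["base"], tr["pseudo_count"], "forced")
            blocks.append(counts.X)
            reports[label] = report
        except DenormalizationFailure as exc:
            blocks.append(sp.csr_matrix(sub.shape))
            reports[label] = {"verdict": "failure", "error": str(exc), "trail": exc.trail}
        order.append(idx)
    if all(isinstance(r, dict) for r in reports.values()):
        raise DenormalizationFailure("every group failed denormalization")
    stacked = sp.vstack(blocks).tocsr()
    perm = np.empty(matrix.n_cells, dtype=np.int64)
    perm[np.concatenate(order)] = np.arange(matrix.n_cells)
    out = GeneExpressionMatrix(
        stacked[perm], matrix.cell_ids, matrix.gene_ids, "counts", {"by_group": True}
    )
    return out, reports
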