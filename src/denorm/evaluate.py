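"""Quantitative evaluation of a denormalization and benchmark harness.

Three metrics:

* **rounding error** ``round(y) - y`` per denormalized entry — near zero iff
  the denormalized values sit on integers;
* **recovery error** ``x - z`` between the original normalized value and the
  value obtained by renormalizing the recovered counts (default
  renormalization: target sum 1e4, pseudo-count 1, natural base);
* **success rate** ``Nsuccess / Ntotal`` over cells, with unsolvable and
  MAE-failed cells kept in the denominator.

`run_benchmark` replays the robustness experiments on synthetic data:
sensitivity to the normalization parameter grid, to reduced storage
precision, and to gene filtering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrix import (
    DeltaParams,
    GeneExpressionMatrix,
    delta_normalize,
    round_half_away,
    round_to_counts,
)
from .unscale import CellScaleSet

__all__ = [
    "DenormReport",
    "rounding_errors",
    "recovery_errors",
    "success_rate",
    "run_benchmark",
    "DEFAULT_PARAM_GRID",
]

#: Renormalization defaults for the recovery error.
RENORM_PARAMS = dict(target_sum=1e4, base=np.e, pseudo_count=1.0)

#: Eight (L, b, p) sets for the parameter-grid benchmark.
DEFAULT_PARAM_GRID: Sequence[tuple] = (
    (1e3, 2.0, 1.0),
    (1e4, 2.0, 1.0),
    (1e5, 2.0, 1.0),
    (1e6, 2.0, 1.0),
    (1e4, np.e, 1.0),
    (1e4, 10.0, 1.0),
    (1e4, np.e, 0.1),
    (1e4, np.e, 0.01),
)


def _summary(err: np.ndarray) -> dict:
    if err.size == 0:
        return {"n": 0, "max": None, "mean": None, "q50": None, "q95": None, "q99": None}
    a = np.abs(err)
    return {
        "n": int(err.size),
        "max": float(a.max()),
        "mean": float(a.mean()),
        "q50": float(np.quantile(a, 0.50)),
        "q95": float(np.quantile(a, 0.95)),
        "q99": float(np.quantile(a, 0.99)),
    }


@dataclass
class DenormReport:
    """Everything a denormalization run learned and how well it did."""

    transform: dict  # fitted base/pseudo-count and provenance
    target_sum: Optional[float]  # inferred L (mode of rounded scaled row sums)
    scale_summary: dict
    rounding: dict
    success_rate: float
    verdict: str  # {success, partial, failure}
    recovery: Optional[dict] = None
    stages: list = field(default_factory=list)
    schema_version: str = "1.0"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def rounding_errors(matrix: GeneExpressionMatrix):
    """Per-entry ``round(y) - y`` and its matrix-level summary."""
    if matrix.stage != "denormalized":
        raise ValueError("rounding_errors expects stage='denormalized'")
    y = matrix.X.data.astype(np.float64)
    err = round_half_away(y) - y
    return err, _summary(err)


def recovery_errors(
    original: GeneExpressionMatrix,
    denormalized: GeneExpressionMatrix,
    params: Optional[DeltaParams] = None,
):
    """Per-entry ``x - z`` between original normalized values and the
    renormalized recovered counts, plus a summary.

    The recovered counts are ``round_to_counts(denormalized)`` renormalized
    with ``params`` (default 1e4 / natural base / pseudo-count 1).  When
    rounding dropped entries the two sparsity patterns differ; errors are
    then taken over the union of stored positions and the number of
    mismatched positions is reported.
    """
    if original.shape != denormalized.shape:
        raise ValueError(
            f"shape mismatch: original {original.shape} vs denormalized {denormalized.shape}"
        )
    params = params or DeltaParams(**RENORM_PARAMS)
    counts = round_to_counts(denormalized)
    renorm = delta_normalize(counts, params)
    diff = (original.X - renorm.X).tocsr()
    diff.eliminate_zeros()
    err = diff.data.astype(np.float64)
    summary = _summary(err)
    if err.size == 0:  # bit-identical renormalization: every error is zero
        summary.update(max=0.0, mean=0.0, q50=0.0, q95=0.0, q99=0.0)
    summary["n_union_positions"] = int(
        (original.X != 0).maximum(renorm.X != 0).sum()
    )
    summary["n_pattern_mismatch"] = int(original.X.nnz + renorm.X.nnz - 2 * (original.X != 0).minimum(renorm.X != 0).sum())
    return err, summary


def success_rate(scales: CellScaleSet) -> float:
    """Nsuccess / Ntotal; unsolvable and failed cells count in Ntotal."""
    if scales.n_cells == 0:
        raise ValueError("success rate is undefined for zero cells")
    return scales.n_success / scales.n_cells


def run_benchmark(
    scenario: str,
    n_cells: int = 300,
    n_genes: int = 1000,
    seed: int = 0,
    param_grid: Sequence[tuple] = DEFAULT_PARAM_GRID,
    decimals: Sequence[int] = tuple(range(2, 9)),
    gene_keep: Sequence[int] = (100, 200, 300, 400, 500, 1000),
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Run one of the robustness scenarios on simulated data.

    ``scenario`` is one of ``param-grid`` (vary the (L, b, p) normalization
    triple), ``precision-sweep`` (store the normalized values at ``d``
    decimals), ``gene-filter-sweep`` (keep only the top-variance genes).
    One row per condition with the max/mean error of denormalized values
    against the true simulated counts, the matrix MAE, the success rate and
    the fitted parameters.  Deterministic for a fixed seed.
    """
    from .pipeline import DenormalizationFailure, denormalize
    from .simulate import degrade_precision, filter_genes, simulate_counts

    counts = simulate_counts(n_cells, n_genes, seed=seed)
    truth = counts.X
    rows_out = []

    def _run(tag: dict, normalized: GeneExpressionMatrix, true_X) -> None:
        row = dict(tag)
        try:
            result, report = denormalize(normalized, seed=seed, **pipeline_kwargs)
            # error of the *denormalized* (pre-rounding) values against truth,
            # over the cells that were successfully recovered (failed cells
            # are flagged in the report, not silently averaged in)
            y = report.denormalized_
            err = None
            if y.X.nnz == true_X.nnz:
                good = report.scales_.success[y.row_index_of_data()]
                err = np.abs(y.X.data - true_X.data)[good]
                if err.size == 0:
                    err = None
            row.update(
                failed=False,
                base=report.transform["base"],
                pseudo_count=report.transform["pseudo_count"],
                fit_objective=report.transform["objective"],
                matrix_mae=report.scale_summary["matrix_mae"],
                success_rate=report.success_rate,
                max_error=float(err.max()) if err is not None else np.nan,
                mean_error=float(err.mean()) if err is not None else np.nan,
            )
        except DenormalizationFailure as exc:
            row.update(
                failed=True,
                base=np.nan,
                pseudo_count=np.nan,
                fit_objective=np.nan,
                matrix_mae=np.nan,
                success_rate=0.0,
                max_error=np.nan,
                mean_error=np.nan,
                failure=str(exc),
            )
        rows_out.append(row)

    if scenario == "param-grid":
        for L, b, p in param_grid:
            params = DeltaParams(target_sum=L, base=b, pseudo_count=p)
            _run(
                {"target_sum": L, "base_true": float(b), "pseudo_true": p},
                delta_normalize(counts, params),
                truth,
            )
    elif scenario == "precision-sweep":
        normalized = delta_normalize(counts, DeltaParams())
        for d in decimals:
            _run(
                {"decimals": d},
                degrade_precision(normalized, "decimals", decimals=d),
                truth,
            )
    elif scenario == "gene-filter-sweep":
        normalized = delta_normalize(counts, DeltaParams())
        for k in gene_keep:
            filtered = filter_genes(normalized, k, strategy="top-variance")
            kept = np.isin(np.asarray(counts.gene_ids), np.asarray(filtered.gene_ids))
            _run({"n_genes_kept": k}, filtered, counts.subset_genes(np.flatnonzero(kept)).X)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return pd.DataFrame(rows_out)
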