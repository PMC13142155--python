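"""Synthetic droplet-like scRNA-seq count data and its degraded derivatives.

Counts are drawn from a negative binomial (Gamma-Poisson) with per-gene means
``mu_j`` and a single dispersion ``phi`` so that the marginal variance at unit
depth is ``nu = mu + phi * mu**2``; ``phi = 0`` degenerates to Poisson.  Gene
means are log-normal (a handful of genes dominate, reproducing the sparsity of
real droplet data) and per-cell depth factors are log-normal as well, giving a
several-fold library-size spread — enough that per-cell scale-factor inference
is non-trivial.

The module also produces the degraded inputs the inversion has to cope with in
the wild: normalized values stored at reduced decimal precision or cast
through IEEE 754 half/single precision, gene-filtered matrices, and
deliberately non-delta "corrupted" matrices used as negative controls.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .matrix import DeltaParams, GeneExpressionMatrix, delta_normalize

__all__ = [
    "NBParams",
    "default_nb_params",
    "simulate_counts",
    "degrade_precision",
    "filter_genes",
    "corrupt_non_delta",
    "simulate_dataset",
]

#: Study-condition defaults: median library size ~2500, dispersion 0.3,
#: log-normal depth spread sigma=0.4, log-normal gene means sigma=1.6.
DEFAULT_MEAN_DEPTH = 2500.0
DEFAULT_DISPERSION = 0.3
DEFAULT_DEPTH_SIGMA = 0.4
DEFAULT_MEAN_SIGMA = 1.6


@dataclass
class NBParams:
    """Negative-binomial generator parameters.

    ``gene_means`` are per-gene means at unit depth; ``dispersion`` is the
    shared overdispersion ``phi`` in ``nu = mu + phi*mu**2``;
    ``depth_factors`` multiply the means per cell.
    """

    gene_means: np.ndarray
    dispersion: float = DEFAULT_DISPERSION
    depth_factors: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.gene_means = np.asarray(self.gene_means, dtype=np.float64)
        if np.any(self.gene_means <= 0):
            raise ValueError("gene_means must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth_factors is not None:
            self.depth_factors = np.asarray(self.depth_factors, dtype=np.float64)
            if np.any(self.depth_factors <= 0):
                raise ValueError("depth_factors must be positive")


def default_nb_params(
    n_cells: int,
    n_genes: int,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
    dispersion: float = DEFAULT_DISPERSION,
    depth_sigma: float = DEFAULT_DEPTH_SIGMA,
    mean_sigma: float = DEFAULT_MEAN_SIGMA,
    seed: int = 0,
) -> NBParams:
    """Draw log-normal gene means (normalized to ``mean_depth`` total) and
    log-normal depth factors (median 1) for the study conditions."""
    rng = np.random.default_rng(seed)
    w = rng.lognormal(0.0, mean_sigma, n_genes)
    mu = mean_depth * w / w.sum()
    depth = rng.lognormal(0.0, depth_sigma, n_cells)
    return NBParams(mu, dispersion, depth, seed)


def simulate_counts(
    n_cells: int,
    n_genes: int,
    nb: Optional[NBParams] = None,
    seed: Optional[int] = None,
    **kwargs,
) -> GeneExpressionMatrix:
    """Draw an integer count matrix NB(mean = depth_i * mu_j, dispersion phi).

    Reproducible for a fixed seed: the seed drives both the parameter draw
    (when ``nb`` is omitted) and the count sampling.  Extra keyword arguments
    are forwarded to :func:`default_nb_params`.
    """
    if n_cells < 1 or n_genes < 1:
        raise ValueError("n_cells and n_genes must be >= 1")
    if nb is None:
        nb = default_nb_params(n_cells, n_genes, seed=0 if seed is None else seed, **kwargs)
    elif kwargs:
        raise TypeError("pass either nb or keyword parameters, not both")
    if nb.gene_means.shape != (n_genes,):
        raise ValueError("gene_means length must equal n_genes")
    depth = nb.depth_factors if nb.depth_factors is not None else np.ones(n_cells)
    if depth.shape != (n_cells,):
        raise ValueError("depth_factors length must equal n_cells")
    rng = np.random.default_rng(nb.seed if seed is None else seed)
    m = depth[:, None] * nb.gene_means[None, :]
    if nb.dispersion == 0:
        counts = rng.poisson(m)
    else:
        r = 1.0 / nb.dispersion
        counts = rng.negative_binomial(r, r / (r + m))
    mat = GeneExpressionMatrix(sp.csr_matrix(counts.astype(np.float64)), stage="counts")
    mat.meta["nb_dispersion"] = nb.dispersion
    return mat


def degrade_precision(
    matrix: GeneExpressionMatrix,
    mode: str = "decimals",
    decimals: Optional[int] = None,
) -> GeneExpressionMatrix:
    """Reduce the storage precision of a normalized matrix.

    ``mode='decimals'`` rounds stored values to ``decimals`` places (>= 1);
    ``'half'`` / ``'single'`` cast through IEEE 754 binary16 / binary32 and
    back to float64.  Sparsity is untouched.
    """
    if matrix.stage != "normalized":
        raise ValueError("degrade_precision expects stage='normalized'")
    data = matrix.X.data.astype(np.float64)
    if mode == "decimals":
        if decimals is None or decimals < 1:
            raise ValueError("decimals must be an integer >= 1")
        data = np.round(data, decimals)
    elif mode == "half":
        data = data.astype(np.float16).astype(np.float64)
    elif mode == "single":
        data = data.astype(np.float32).astype(np.float64)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = matrix.with_data(data, "normalized")
    out.meta["precision"] = mode if mode != "decimals" else f"decimals={decimals}"
    return out


def filter_genes(
    matrix: GeneExpressionMatrix,
    n_keep: int,
    strategy: str = "top-variance",
    seed: int = 0,
) -> GeneExpressionMatrix:
    """Restrict the matrix to ``n_keep`` genes (original column order kept).

    ``top-variance`` keeps the genes with the largest variance (the
    highly-variable-gene selection emulated here); ``random`` keeps a uniform
    sample.  Cells emptied by the filter are retained and flagged in
    ``meta['emptied_cells']``.
    """
    if not 1 <= n_keep <= matrix.n_genes:
        raise ValueError("n_keep must be in [1, n_genes]")
    if strategy == "top-variance":
        X = matrix.X
        n = X.shape[0]
        s1 = np.asarray(X.sum(axis=0)).ravel() / n
        s2 = np.asarray(X.multiply(X).sum(axis=0)).ravel() / n
        var = s2 - s1**2
        keep = np.sort(np.argsort(-var, kind="stable")[:n_keep])
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(matrix.n_genes, size=n_keep, replace=False))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    out = matrix.subset_genes(keep)
    emptied = np.flatnonzero(np.diff(out.X.indptr) == 0)
    out.meta["emptied_cells"] = emptied.tolist()
    return out


def corrupt_non_delta(
    matrix: GeneExpressionMatrix, mode: str = "length-scaled", seed: int = 0
) -> GeneExpressionMatrix:
    """Produce matrices that violate the delta model (negative controls).

    ``length-scaled``
        TPM-like: counts divided by a per-gene "transcript length" before
        library normalization and log2 — the per-gene factor destroys the
        within-cell integer value ladder.
    ``residual-like``
        log values z-scored per gene over stored entries — mean-centered,
        contains negatives, no ladder at all.
    ``passthrough``
        No corruption; the control arm.
    """
    if matrix.stage != "counts":
        raise ValueError("corrupt_non_delta expects stage='counts'")
    if mode == "passthrough":
        return matrix.copy()
    rng = np.random.default_rng(seed)
    rows = matrix.row_index_of_data()
    if mode == "length-scaled":
        lengths = rng.lognormal(0.0, 0.5, matrix.n_genes)
        rate = matrix.X.data / lengths[matrix.X.indices]
        rate_mat = matrix.with_data(rate, "scaled")
        per_cell = rate_mat.row_sums()
        tpm = rate * (1e6 / per_cell[rows])
        data = np.log2(tpm + 1.0)
    elif mode == "residual-like":
        logged = np.log1p(matrix.X.data * (1e4 / matrix.row_sums()[rows]))
        col = matrix.X.indices
        sums = np.bincount(col, weights=logged, minlength=matrix.n_genes)
        cnts = np.bincount(col, minlength=matrix.n_genes).astype(np.float64)
        mean = np.divide(sums, cnts, out=np.zeros_like(sums), where=cnts > 0)
        sq = np.bincount(col, weights=(logged - mean[col]) ** 2, minlength=matrix.n_genes)
        sd = np.sqrt(np.divide(sq, np.maximum(cnts - 1, 1.0)))
        sd[sd == 0] = 1.0
        data = (logged - mean[col]) / sd[col]
        data[data == 0] = 1e-12  # keep the sparsity pattern intact
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = matrix.with_data(data, "normalized")
    out.meta["corruption"] = mode
    return out


def simulate_dataset(
    n_cells: int,
    n_genes: int,
    params: Optional[DeltaParams] = None,
    seed: int = 0,
    normalize: bool = True,
    **nb_kwargs,
) -> tuple:
    """Convenience: simulate counts and (optionally) their normalized image.

    Returns ``(counts, normalized_or_None, params, manifest)`` where the
    manifest records the ground truth needed by benchmark harnesses: the seed,
    generator settings and the normalization triple.
    """
    counts = simulate_counts(n_cells, n_genes, seed=seed, **nb_kwargs)
    params = params or DeltaParams()
    params = dataclasses.replace(params, cell_totals=counts.row_sums())
    normalized = delta_normalize(counts, params) if normalize else None
    manifest = {
        "seed": seed,
        "n_cells": n_cells,
        "n_genes": n_genes,
        "generator": {
            "mean_depth": nb_kwargs.get("mean_depth", DEFAULT_MEAN_DEPTH),
            "dispersion": nb_kwargs.get("dispersion", DEFAULT_DISPERSION),
            "depth_sigma": nb_kwargs.get("depth_sigma", DEFAULT_DEPTH_SIGMA),
            "mean_sigma": nb_kwargs.get("mean_sigma", DEFAULT_MEAN_SIGMA),
        },
        "delta_params": {
            "target_sum": params.target_sum,
            "base": params.base if params.base == "no-log" else float(params.base),
            "pseudo_count": params.pseudo_count,
        },
    }
    return counts, normalized, params, manifest
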