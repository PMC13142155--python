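"""Reading and writing expression matrices in the field's standard formats.

Three on-disk representations are supported, all round-tripping through
:class:`~denorm.matrix.GeneExpressionMatrix`:

``mtx-dir``
    A directory with ``matrix.mtx`` (Matrix Market coordinate format, 1-based
    indices handled by :mod:`scipy.io`), ``barcodes.tsv`` (one cell id per
    line) and ``features.tsv`` (one gene id per line).  Rows of the matrix are
    cells; a CellRanger-style genes x cells file is read with
    ``transposed=True`` — orientation is an explicit flag, never guessed.
``h5-container``
    An AnnData ``.h5ad`` file (cells as obs, genes as var).  Layers,
    embeddings and graphs present in the container are ignored on read and
    not produced on write.
``delimited``
    Dense text (TSV/CSV): header row of gene ids, first column of cell
    barcodes.  Zeros in the dense table are not stored.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.io

from .matrix import GeneExpressionMatrix

__all__ = ["read_matrix", "write_matrix", "detect_format", "save_json"]

_MTX_NAMES = ("matrix.mtx", "barcodes.tsv", "features.tsv")


def detect_format(path: str) -> str:
    """Infer the container format from the path (directory => mtx-dir)."""
    if os.path.isdir(path):
        return "mtx-dir"
    if path.endswith((".h5ad", ".h5")):
        return "h5-container"
    return "delimited"


def read_matrix(
    path: str,
    format: Optional[str] = None,
    stage: str = "counts",
    transposed: bool = False,
    sep: str = "\t",
) -> GeneExpressionMatrix:
    """Read an expression matrix; see the module docstring for the formats.

    Raises ``ValueError`` on a dimension mismatch between the matrix and its
    barcode/feature sidecars, and ``FileNotFoundError`` for missing pieces.
    """
    fmt = format or detect_format(path)
    if fmt == "mtx-dir":
        mtx, bc, ft = (os.path.join(path, n) for n in _MTX_NAMES)
        for f in (mtx, bc, ft):
            if not os.path.exists(f):
                raise FileNotFoundError(f"mtx-dir is missing {os.path.basename(f)}")
        X = sp.csr_matrix(scipy.io.mmread(mtx))
        cells = pd.read_csv(bc, header=None, sep=sep)[0].astype(str).tolist()
        genes = pd.read_csv(ft, header=None, sep=sep)[0].astype(str).tolist()
        if transposed:
            X = X.T.tocsr()
        if X.shape != (len(cells), len(genes)):
            raise ValueError(
                f"matrix shape {X.shape} does not match sidecars "
                f"({len(cells)} barcodes, {len(genes)} features)"
            )
        return GeneExpressionMatrix(X, cells, genes, stage)
    if fmt == "h5-container":
        import anndata as ad

        adata = ad.read_h5ad(path)
        X = sp.csr_matrix(adata.X)
        if transposed:
            X = X.T.tocsr()
        return GeneExpressionMatrix(
            X, adata.obs_names.astype(str).tolist(), adata.var_names.astype(str).tolist(), stage
        )
    if fmt == "delimited":
        df = pd.read_csv(path, sep=sep, index_col=0)
        X = sp.csr_matrix(df.to_numpy(dtype=np.float64))
        if transposed:
            df = df.T
            X = sp.csr_matrix(df.to_numpy(dtype=np.float64))
        return GeneExpressionMatrix(
            X, df.index.astype(str).tolist(), df.columns.astype(str).tolist(), stage
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_matrix(
    matrix: GeneExpressionMatrix,
    path: str,
    format: Optional[str] = None,
    sep: str = "\t",
) -> None:
    """Write a matrix in any of the supported formats (see :func:`read_matrix`)."""
    fmt = format or detect_format(path)
    if fmt == "mtx-dir":
        os.makedirs(path, exist_ok=True)
        mtx, bc, ft = (os.path.join(path, n) for n in _MTX_NAMES)
        X = matrix.X.tocoo()
        if matrix.stage == "counts":
            X = X.astype(np.int64)
        scipy.io.mmwrite(mtx, X)
        pd.Series(matrix.cell_ids).to_csv(bc, index=False, header=False, sep=sep)
        pd.Series(matrix.gene_ids).to_csv(ft, index=False, header=False, sep=sep)
        return
    if fmt == "h5-container":
        import anndata as ad

        adata = ad.AnnData(
            X=matrix.X.copy(),
            obs=pd.DataFrame(index=pd.Index(matrix.cell_ids, name="barcode")),
            var=pd.DataFrame(index=pd.Index(matrix.gene_ids, name="feature")),
        )
        adata.uns["stage"] = matrix.stage
        adata.write_h5ad(path)
        return
    if fmt == "delimited":
        arr = matrix.X.toarray()
        if matrix.stage == "counts":
            arr = arr.astype(np.int64)
        pd.DataFrame(arr, index=matrix.cell_ids, columns=matrix.gene_ids).to_csv(path, sep=sep)
        return
    raise ValueError(f"unknown format {fmt!r}")


def save_json(obj: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
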