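"""Cell quality control and normalization.

QC metrics are the usual droplet triple: genes detected per cell, UMIs per
cell, and the percentage of UMIs from mitochondrially encoded genes. Cells
with more than 20% mitochondrial reads are removed (a strict > rule: exactly
20% survives), together with cells below the detected-gene and UMI floors.
Normalization follows the counts-per-million convention with a natural-log
log1p transform.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["qc_metrics", "filter_cells", "normalize_cpm_log"]

MITO_MAX_PCT = 20.0
MIN_GENES = 200
MIN_UMI = 500


def qc_metrics(
    X: sp.spmatrix,
    genes: pd.Index,
    barcodes: pd.Index,
    mito_genes: list[str] | set[str],
) -> pd.DataFrame:
    """Per-cell QC metrics from a cells x genes count matrix.

    Returns ``n_genes`` (genes with >= 1 UMI), ``n_umi`` and ``pct_mito``
    (mitochondrial UMI share in percent; defined as 0 for an all-zero cell).
    """
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("empty count matrix")
    mito_genes = set(mito_genes)
    unknown = mito_genes - set(genes)
    if unknown:
        raise ValueError(f"mito genes not in gene universe: {sorted(unknown)}")
    X = sp.csr_matrix(X)
    n_umi = np.asarray(X.sum(axis=1)).ravel()
    n_genes = X.getnnz(axis=1)
    mito_cols = np.flatnonzero(genes.isin(mito_genes))
    mito_umi = (
        np.asarray(X[:, mito_cols].sum(axis=1)).ravel()
        if len(mito_cols)
        else np.zeros_like(n_umi)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(n_umi > 0, 100.0 * mito_umi / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "n_genes": n_genes.astype(np.int64),
            "n_umi": n_umi.astype(np.int64),
            "pct_mito": pct,
        },
        index=barcodes,
    )


def filter_cells(
    metrics: pd.DataFrame,
    mito_max: float = MITO_MAX_PCT,
    min_genes: int = MIN_GENES,
    min_umi: int = MIN_UMI,
) -> pd.Series:
    """Boolean keep-mask: a cell is removed iff pct_mito > mito_max (strict)
    or it falls below the detected-gene / UMI floors (floors are inclusive).

    Idempotent by construction: re-filtering survivors removes nothing.
    """
    if mito_max < 0 or min_genes < 0 or min_umi < 0:
        raise ValueError("thresholds must be nonnegative")
    keep = (
        (metrics["pct_mito"] <= mito_max)
        & (metrics["n_genes"] >= min_genes)
        & (metrics["n_umi"] >= min_umi)
    )
    keep.name = "keep"
    return keep


def normalize_cpm_log(X: sp.spmatrix) -> sp.csr_matrix:
    """Counts-per-million per cell, then log(1 + x).

    Zero-total cells map to all-zero rows; the zero pattern of the matrix is
    preserved exactly.
    """
    X = sp.csr_matrix(X, dtype=np.float64, copy=True)
    totals = np.asarray(X.sum(axis=1)).ravel()
    scale = np.divide(
        1e6, totals, out=np.zeros_like(totals, dtype=np.float64), where=totals > 0
    )
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    return sp.csr_matrix(X)
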