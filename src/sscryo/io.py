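"""Standard-format I/O: 10x-style MatrixMarket count triplets, TSV tables,
and flat YAML configuration files.

Count matrices are stored on disk genes x cells (rows = features, 1-based
coordinate MTX, integer field) alongside ``features.tsv`` and
``barcodes.tsv``; in memory everything is cells x genes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from scipy.io import mmread, mmwrite

__all__ = [
    "read_counts_mtx",
    "write_counts_mtx",
    "read_dual_counts",
    "write_dual_counts",
    "read_config_yaml",
    "write_config_yaml",
]

MTX_NAME = "matrix.mtx"
FEATURES_NAME = "features.tsv"
BARCODES_NAME = "barcodes.tsv"


def read_counts_mtx(path: str | Path):
    """Read a matrix.mtx + features.tsv + barcodes.tsv triplet.

    Returns ``(X, genes, barcodes)`` with X a cells x genes CSR matrix of
    integer counts. Dimension mismatches between the three files and
    non-integer matrix entries are errors.
    """
    path = Path(path)
    mat = mmread(path / MTX_NAME)  # genes x cells on disk
    genes = pd.Index(
        pd.read_csv(path / FEATURES_NAME, sep="\t", header=None)[0], name="gene"
    )
    barcodes = pd.Index(
        pd.read_csv(path / BARCODES_NAME, sep="\t", header=None)[0], name="barcode"
    )
    if mat.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix is {mat.shape} but features/barcodes give "
            f"({len(genes)}, {len(barcodes)})"
        )
    data = mat.data if sp.issparse(mat) else np.asarray(mat).ravel()
    if not np.allclose(data, np.round(data)):
        raise ValueError("non-integer entries in count matrix")
    X = sp.csr_matrix(mat.T).astype(np.int64)
    return X, genes, barcodes


def write_counts_mtx(
    X: sp.spmatrix,
    genes: pd.Index,
    barcodes: pd.Index,
    path: str | Path,
) -> Path:
    """Write a cells x genes count matrix as a genes x cells MTX triplet."""
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("refusing to write an empty count matrix")
    if X.shape != (len(barcodes), len(genes)):
        raise ValueError("matrix shape inconsistent with gene/barcode labels")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    mmwrite(
        path / MTX_NAME,
        sp.coo_matrix(X.T),
        field="integer",
        comment="genes x cells UMI counts",
    )
    pd.Series(list(genes)).to_csv(
        path / FEATURES_NAME, sep="\t", header=False, index=False
    )
    pd.Series(list(barcodes)).to_csv(
        path / BARCODES_NAME, sep="\t", header=False, index=False
    )
    return path


def write_dual_counts(counts, outdir: str | Path) -> Path:
    """Write the rat- and mouse-aligned triplets under ``outdir``/{rat,mouse}."""
    outdir = Path(outdir)
    write_counts_mtx(counts.rat, counts.rat_genes, counts.barcodes, outdir / "rat")
    write_counts_mtx(
        counts.mouse, counts.mouse_genes, counts.barcodes, outdir / "mouse"
    )
    return outdir


def read_dual_counts(indir: str | Path):
    """Read back a dual-species directory written by :func:`write_dual_counts`."""
    from .simulate import DualSpeciesCounts

    indir = Path(indir)
    rat, rat_genes, bc_r = read_counts_mtx(indir / "rat")
    mouse, mouse_genes, bc_m = read_counts_mtx(indir / "mouse")
    if not bc_r.equals(bc_m):
        raise ValueError("rat and mouse triplets disagree on barcodes")
    return DualSpeciesCounts(
        rat=sp.csr_matrix(rat, dtype=np.int32),
        mouse=sp.csr_matrix(mouse, dtype=np.int32),
        rat_genes=rat_genes,
        mouse_genes=mouse_genes,
        barcodes=bc_r,
    )


def write_config_yaml(config_dict: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=False)
    return path


def read_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return out
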