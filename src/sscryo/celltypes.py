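"""Unsupervised clustering, marker-panel germ-cell typing, and a simplified
linear pseudotime.

Typing works cluster-wise: cells are clustered without supervision, each
cluster is scored against every marker panel (mean normalized expression of
the panel's genes over the cluster's cells), and the whole cluster inherits
the best-scoring panel's label. Pseudotime is deliberately simple — the first
principal component of normalized expression rescaled to [0, 1] and oriented
so that cells high in the start gene (*Etv5*, the stem-cell end) sit low —
because the lineage is a largely linear, unbranched progression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .markers import MARKER_PANELS, STAGES

__all__ = [
    "cluster_cells",
    "score_marker_panels",
    "annotate_cells",
    "linear_pseudotime",
]

N_PCS = 20
DEFAULT_K = 12  # over-cluster relative to the 7 panels; labels collapse clusters


def _to_dense(X: sp.spmatrix | np.ndarray) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X, dtype=np.float64)


def cluster_cells(
    X_norm: sp.spmatrix | np.ndarray,
    k: int | None = None,
    seed: int = 0,
    n_pcs: int = N_PCS,
) -> np.ndarray:
    """Centroid-based clustering of normalized expression.

    Cells are reduced to the top principal components, then partitioned with
    k-means. By default k over-clusters relative to the seven germ-cell
    panels; the typing step labels each cluster by its best panel, so several
    clusters may collapse onto one cell type. Deterministic under ``seed``.
    """
    n_cells = X_norm.shape[0]
    if k is None:
        k = min(DEFAULT_K, n_cells)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_cells:
        raise ValueError(f"k={k} exceeds the number of cells ({n_cells})")
    if k == 1:
        return np.zeros(n_cells, dtype=np.int64)
    dense = _to_dense(X_norm)
    n_comp = min(n_pcs, n_cells - 1, dense.shape[1])
    if n_comp >= 1:
        dense = PCA(n_components=n_comp, random_state=seed).fit_transform(dense)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(dense).astype(np.int64)


def score_marker_panels(
    X_norm: sp.spmatrix | np.ndarray,
    genes: pd.Index,
    panels: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Per-cell panel scores: mean normalized expression of each panel's genes.

    Raises a KeyError naming the first panel gene absent from the universe.
    """
    panels = MARKER_PANELS if panels is None else panels
    pos = {g: i for i, g in enumerate(genes)}
    cols = {}
    X_norm = sp.csc_matrix(X_norm) if sp.issparse(X_norm) else np.asarray(X_norm)
    for panel, panel_genes in panels.items():
        idx = []
        for g in panel_genes:
            if g not in pos:
                raise KeyError(f"marker gene {g!r} not present in gene universe")
            idx.append(pos[g])
        sub = X_norm[:, idx]
        cols[panel] = np.asarray(sub.mean(axis=1)).ravel()
    return pd.DataFrame(cols)


def annotate_cells(
    clusters: np.ndarray,
    panel_scores: pd.DataFrame,
    stage_order: tuple[str, ...] = STAGES,
) -> pd.Series:
    """Label every cluster with its best-scoring panel; cells inherit it.

    Ties between panels are broken by canonical stage order (earliest wins).
    """
    clusters = np.asarray(clusters)
    if len(clusters) != len(panel_scores):
        raise ValueError("one panel-score row per cell required")
    ordered = [s for s in stage_order if s in panel_scores.columns]
    extra = [c for c in panel_scores.columns if c not in ordered]
    scores = panel_scores[ordered + extra]
    labels = pd.Series(index=panel_scores.index, dtype="object", name="cell_type")
    for c in np.unique(clusters):
        mean_scores = scores.loc[clusters == c].mean(axis=0)
        # idxmax keeps the first (earliest-stage) column on ties
        labels.loc[clusters == c] = mean_scores.idxmax()
    return labels


def linear_pseudotime(
    X_norm: sp.spmatrix | np.ndarray,
    genes: pd.Index,
    start_gene: str = "Etv5",
) -> np.ndarray:
    """Project cells on PC1 of normalized expression, rescaled to [0, 1].

    The sign of the axis is fixed by the start gene: cells in the top decile
    of ``start_gene`` expression must have mean pseudotime below 0.5, so the
    stem-cell end of the lineage sits near 0 regardless of the arbitrary PCA
    sign.
    """
    if X_norm.shape[0] < 2:
        raise ValueError("pseudotime requires at least 2 cells")
    if start_gene not in set(genes):
        raise KeyError(f"start gene {start_gene!r} not present in gene universe")
    dense = _to_dense(X_norm)
    pc1 = PCA(n_components=1, random_state=0).fit_transform(dense).ravel()
    span = pc1.max() - pc1.min()
    t = (pc1 - pc1.min()) / span if span > 0 else np.zeros_like(pc1)
    expr = dense[:, list(genes).index(start_gene)]
    n_top = max(1, len(expr) // 10)
    top = np.argsort(expr, kind="stable")[-n_top:]
    if t[top].mean() > 0.5:
        t = 1.0 - t
    return t
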