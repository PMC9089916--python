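"""Replicate-level pseudobulk profiles, PCA, and PERMANOVA.

Single cells are not independent samples: biological inference across
treatments is done on pseudobulk profiles, the mean normalized expression of
all of one replicate's cells of a given type. Treatment separation of those
profiles is tested with a one-way PERMANOVA (Anderson's pseudo-F on a
distance matrix, null distribution by label permutation). The distance metric
defaults to Euclidean on log-CPM pseudobulk profiles.

The pseudo-F is computed from the distance matrix alone:

    SS_total  = sum_{i<j} d_ij^2 / N
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    F = ((SS_total - SS_within) / (a - 1)) / (SS_within / (N - a))

with N samples in a groups. The permutation p-value uses the add-one
convention p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations), so p is never
zero; an exhaustive mode enumerates every distinct relabeling instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as _PCA

logger = logging.getLogger(__name__)

__all__ = [
    "pseudobulk_mean",
    "pca",
    "distance_matrix",
    "permanova",
    "pooled_group_design",
    "PermanovaResult",
]


def pseudobulk_mean(
    X_norm: sp.spmatrix | np.ndarray,
    genes: pd.Index,
    obs: pd.DataFrame,
    cell_type: str,
    celltype_col: str = "cell_type",
    replicate_col: str = "replicate",
    treatment_col: str = "treatment",
) -> pd.DataFrame:
    """Mean normalized expression per (replicate, treatment) over cells of one type.

    Rows are indexed by replicate, carry a ``treatment`` and ``n_cells``
    column plus one column per gene. Replicates with no cells of the type are
    omitted with a logged warning.
    """
    X_norm = sp.csr_matrix(X_norm) if sp.issparse(X_norm) else np.asarray(X_norm)
    mask = (obs[celltype_col] == cell_type).to_numpy()
    rows = []
    index = []
    for (rep, treat), sub in obs.groupby([replicate_col, treatment_col], sort=True):
        sel = np.flatnonzero(mask & obs.index.isin(sub.index))
        if sel.size == 0:
            logger.warning(
                "replicate %s has no %r cells; pseudobulk row omitted", rep, cell_type
            )
            continue
        mean = np.asarray(X_norm[sel].mean(axis=0)).ravel()
        rows.append(
            pd.Series(mean, index=genes).to_dict()
            | {"treatment": treat, "n_cells": int(sel.size)}
        )
        index.append(rep)
    out = pd.DataFrame(rows, index=pd.Index(index, name="replicate"))
    if not out.empty:
        out = out[["treatment", "n_cells"] + list(genes)]
    return out


def _values(pb: pd.DataFrame) -> np.ndarray:
    cols = [c for c in pb.columns if c not in ("treatment", "n_cells")]
    return pb[cols].to_numpy(dtype=np.float64)


def pca(pb: pd.DataFrame | np.ndarray, n_components: int | None = None):
    """PCA of pseudobulk rows: (coordinates, percent variance per component).

    A constant matrix yields all-zero coordinates and 0% variance shares.
    """
    X = _values(pb) if isinstance(pb, pd.DataFrame) else np.asarray(pb, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 rows")
    n_comp = n_components or min(X.shape[0] - 1, X.shape[1])
    model = _PCA(n_components=n_comp, random_state=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        coords = model.fit_transform(X)
    total = model.explained_variance_.sum()
    if total > 0:
        var_pct = 100.0 * model.explained_variance_ / total
    else:
        var_pct = np.zeros(n_comp)
    return coords, var_pct


def distance_matrix(
    pb: pd.DataFrame | np.ndarray, metric: str = "euclidean"
) -> np.ndarray:
    """Symmetric pairwise distance matrix between pseudobulk rows."""
    X = _values(pb) if isinstance(pb, pd.DataFrame) else np.asarray(pb, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("NaN values in pseudobulk matrix")
    return squareform(pdist(X, metric=metric))


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]
    method: str = "permutation"


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    distances: np.ndarray,
    group_labels,
    n_permutations: int = 1000,
    seed: int | None = None,
    method: str = "permutation",
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``method="permutation"`` draws ``n_permutations`` random relabelings and
    applies the add-one p-value; ``method="exhaustive"`` enumerates every
    distinct assignment of the label multiset (feasible only for small N) and
    reports the exact fraction of assignments, the observed one included,
    with F at least as extreme.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distances must be a square matrix")
    labels = pd.Series(list(group_labels))
    if len(labels) != d.shape[0]:
        raise ValueError("one label per distance-matrix row required")
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    codes = labels.map({u: i for i, u in enumerate(uniq)}).to_numpy()
    sizes = {str(u): int((labels == u).sum()) for u in uniq}
    d2 = d**2
    f_obs = _pseudo_f(d2, codes, len(uniq))

    if method == "exhaustive":
        from sympy.utilities.iterables import multiset_permutations

        hits = 0
        total = 0
        for perm in multiset_permutations(list(codes)):
            total += 1
            if _pseudo_f(d2, np.asarray(perm), len(uniq)) >= f_obs - 1e-12:
                hits += 1
        return PermanovaResult(
            pseudo_F=float(f_obs),
            p_value=hits / total,
            n_permutations=total,
            group_sizes=sizes,
            method="exhaustive",
        )
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, len(uniq)) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        group_sizes=sizes,
    )


def pooled_group_design(
    treatments, pooling: dict[str, str] | None = None
) -> pd.Series:
    """Map per-row treatments to pooled test groups.

    ``pooling`` maps each treatment to its pooled group label (e.g. both
    frozen arms to ``"frozen"``); every treatment present must be mapped.
    With ``pooling=None`` the treatments are used as-is.
    """
    treatments = pd.Series(list(treatments), name="group")
    if pooling is None:
        return treatments
    unmapped = sorted(set(treatments) - set(pooling))
    if unmapped:
        raise KeyError(f"treatments missing from pooling spec: {unmapped}")
    return treatments.map(pooling).rename("group")
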