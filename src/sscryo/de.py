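"""Per-gene two-group differential expression within a cell type.

Cells from both groups are pooled across replicates and compared gene-by-gene
with a two-sided Wilcoxon rank-sum (Mann-Whitney U) test — tie-corrected
normal approximation with continuity correction, switching to the exact
distribution for very small tie-free groups. Fold changes are computed on
CPM-scale group means with a pseudocount of 1, p-values are adjusted by
Benjamini-Hochberg, and a gene is called significant when it clears both the
minimum 1.5-fold change (|log2FC| >= log2 1.5) and the adjusted-p <= 0.05
cutoffs, inclusive at both boundaries.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wilcoxon_de",
    "bh_adjust",
    "apply_deg_cutoffs",
    "overlap_sets",
    "FC_MIN",
    "PADJ_MAX",
]

FC_MIN = 1.5
PADJ_MAX = 0.05
EXACT_MAX_N = 7  # exact rank-sum distribution below 8 cells per group


def _cpm(X: sp.spmatrix | np.ndarray) -> np.ndarray:
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=np.float64)
    totals = X.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(totals > 0, 1e6 * X / np.maximum(totals, 1), 0.0)


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney p per gene (columns of a and b)."""
    n_genes = a.shape[1]
    p = np.ones(n_genes)
    small = min(a.shape[0], b.shape[0]) <= EXACT_MAX_N
    for j in range(n_genes):
        x, y = a[:, j], b[:, j]
        if np.ptp(np.concatenate([x, y])) == 0:
            continue  # all values identical: no evidence either way
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if small and not has_ties else "asymptotic"
        p[j] = mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    return p


def _rank_sum_p_vectorized(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    # all-tied genes yield nan under the tie-corrected normal approximation
    flat = np.array(
        [np.ptp(np.concatenate([a[:, j], b[:, j]])) == 0 for j in range(a.shape[1])]
    )
    p[flat | ~np.isfinite(p)] = 1.0
    return np.clip(p, 0.0, 1.0)


def wilcoxon_de(
    X_counts: sp.spmatrix | np.ndarray,
    genes: pd.Index,
    obs: pd.DataFrame,
    group_a: str,
    group_b: str,
    cell_type: str | None = None,
    group_col: str = "treatment",
    celltype_col: str = "cell_type",
    fc_min: float = FC_MIN,
    padj_max: float = PADJ_MAX,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE of group_a vs group_b, optionally within one cell type.

    Returns one row per gene: group mean CPM, log2 fold change
    (log2((mean_A + 1) / (mean_B + 1))), raw and BH-adjusted p, and the
    significance flag at the fold-change / adjusted-p cutoffs.
    """
    sel = np.ones(len(obs), dtype=bool)
    if cell_type is not None:
        sel &= (obs[celltype_col] == cell_type).to_numpy()
    in_a = sel & (obs[group_col] == group_a).to_numpy()
    in_b = sel & (obs[group_col] == group_b).to_numpy()
    if not in_a.any() or not in_b.any():
        raise ValueError(
            f"empty group for {group_a!r} vs {group_b!r}"
            + (f" in cell type {cell_type!r}" if cell_type else "")
        )
    X = sp.csr_matrix(X_counts) if sp.issparse(X_counts) else np.asarray(X_counts)
    cpm_a = _cpm(X[np.flatnonzero(in_a)])
    cpm_b = _cpm(X[np.flatnonzero(in_b)])
    mean_a = cpm_a.mean(axis=0)
    mean_b = cpm_b.mean(axis=0)
    log2_fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    if min(cpm_a.shape[0], cpm_b.shape[0]) <= EXACT_MAX_N:
        p = _rank_sum_p(cpm_a, cpm_b)
    else:
        p = _rank_sum_p_vectorized(cpm_a, cpm_b)
    padj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "gene": list(genes),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fold_change": log2_fc,
            "p_value": p,
            "p_adjusted": padj,
        }
    ).set_index("gene")
    out["significant"] = (np.abs(out["log2_fold_change"]) >= np.log2(fc_min)) & (
        out["p_adjusted"] <= padj_max
    )
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_deg_cutoffs(
    results: pd.DataFrame, fc_min: float = FC_MIN, padj_max: float = PADJ_MAX
) -> set[str]:
    """Significant gene set at the fold-change and FDR cutoffs (inclusive)."""
    if results.empty:
        return set()
    flag = (np.abs(results["log2_fold_change"]) >= np.log2(fc_min)) & (
        results["p_adjusted"] <= padj_max
    )
    return set(results.index[flag])


def overlap_sets(deg_sets: dict[str, set]) -> dict[str, int]:
    """Exclusive-region counts of an Euler diagram over >= 2 gene sets.

    Keys name the sets containing a region's elements, joined by ``&``; the
    counts partition the union of all sets.
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(deg_sets)
    counts: dict[str, int] = {}
    for membership in product([False, True], repeat=len(names)):
        if not any(membership):
            continue
        region = set.intersection(
            *(set(deg_sets[n]) for n, m in zip(names, membership) if m)
        )
        for n, m in zip(names, membership):
            if not m:
                region -= set(deg_sets[n])
        key = "&".join(n for n, m in zip(names, membership) if m)
        counts[key] = len(region)
    assert sum(counts.values()) == len(set.union(*(set(s) for s in deg_sets.values())))
    return counts
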