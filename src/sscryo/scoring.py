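"""Gene-program module scoring, apoptotic classification, and cell-type
proportion statistics.

The module score of a gene program in a cell is the mean normalized
expression of the program's genes minus the mean of an expression-matched
control set: all genes are binned by their average expression across cells
(equal-frequency bins), and for every program gene a fixed number of control
genes is drawn from its bin. Subtracting bin-matched controls removes depth
and baseline-expression effects, so a score near 0 means "no more active than
comparable genes". A cell is classified apoptotic when its proapoptotic-
program score exceeds 0.1 (a strict > rule at a deliberately arbitrary
cutoff).

Cell-type composition is summarized per replicate as a row-normalized
proportion table and compared across treatments with an ordinary one-way
ANOVA per cell type, as is standard for replicate-level composition data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import f_oneway

from .markers import PROAPOPTOTIC_GENES

__all__ = [
    "GeneProgram",
    "PROAPOPTOTIC_PROGRAM",
    "module_score",
    "classify_apoptotic",
    "celltype_proportions",
    "anova_per_celltype",
    "APOPTOSIS_CUTOFF",
]

APOPTOSIS_CUTOFF = 0.1
N_BINS = 25
N_CTRL = 100


class GeneProgram:
    """A named, duplicate-free gene list."""

    def __init__(self, name: str, genes):
        genes = list(genes)
        if not genes:
            raise ValueError("gene program must be nonempty")
        if len(set(genes)) != len(genes):
            raise ValueError("gene program contains duplicates")
        self.name = name
        self.genes = tuple(genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __repr__(self) -> str:
        return f"GeneProgram({self.name!r}, {len(self.genes)} genes)"


PROAPOPTOTIC_PROGRAM = GeneProgram("proapoptotic", PROAPOPTOTIC_GENES)


def module_score(
    X_norm: sp.spmatrix | np.ndarray,
    genes: pd.Index,
    program: GeneProgram,
    n_bins: int = N_BINS,
    n_ctrl: int = N_CTRL,
    seed: int | None = 0,
) -> np.ndarray:
    """Per-cell program score with binned control genes.

    score(cell) = mean(program genes) - mean(control pool), where the control
    pool is the union, over program genes, of ``n_ctrl`` genes sampled
    without replacement from the program gene's average-expression bin (the
    whole bin if it is smaller). Deterministic under ``seed``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    pos = {g: i for i, g in enumerate(genes)}
    prog_idx = []
    for g in program.genes:
        if g not in pos:
            raise KeyError(f"program gene {g!r} not present in gene universe")
        prog_idx.append(pos[g])
    prog_idx = np.asarray(prog_idx)

    dense = X_norm.toarray() if sp.issparse(X_norm) else np.asarray(X_norm, float)
    avg = dense.mean(axis=0)
    order = np.argsort(avg, kind="stable")
    bin_of = np.empty(len(genes), dtype=np.int64)
    bin_of[order] = np.arange(len(genes)) * n_bins // len(genes)

    rng = np.random.default_rng(seed)
    ctrl: set[int] = set()
    for gi in prog_idx:
        members = np.flatnonzero(bin_of == bin_of[gi])
        if len(members) <= n_ctrl:
            ctrl.update(members.tolist())
        else:
            ctrl.update(rng.choice(members, size=n_ctrl, replace=False).tolist())
    ctrl_idx = np.fromiter(sorted(ctrl), dtype=np.int64)

    return dense[:, prog_idx].mean(axis=1) - dense[:, ctrl_idx].mean(axis=1)


def classify_apoptotic(
    scores: np.ndarray | pd.Series,
    obs: pd.DataFrame | None = None,
    cutoff: float = APOPTOSIS_CUTOFF,
    replicate_col: str = "replicate",
    celltype_col: str = "cell_type",
):
    """Flag cells with score strictly above the cutoff.

    Returns the per-cell boolean flags; when ``obs`` is given, also the
    apoptotic fraction per (replicate, cell type).
    """
    values = np.asarray(scores, dtype=float)
    flags = values > cutoff
    if obs is None:
        return flags
    frame = obs[[replicate_col, celltype_col]].copy()
    frame["apoptotic"] = flags
    fractions = (
        frame.groupby([replicate_col, celltype_col], observed=True)["apoptotic"]
        .mean()
        .rename("apoptotic_fraction")
        .reset_index()
    )
    return flags, fractions


def celltype_proportions(
    obs: pd.DataFrame,
    replicate_col: str = "replicate",
    treatment_col: str = "treatment",
    celltype_col: str = "cell_type",
) -> pd.DataFrame:
    """Row-normalized cell-type fractions per (treatment, replicate).

    Every row sums to 1; an empty replicate is an error.
    """
    if obs.empty:
        raise ValueError("no cells to tabulate")
    if obs[celltype_col].isna().any():
        raise ValueError("every cell must carry a cell type")
    counts = (
        obs.groupby([treatment_col, replicate_col, celltype_col], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("empty replicate in proportion table")
    props = counts.div(totals, axis=0)
    props.columns.name = "cell_type"
    return props


def anova_per_celltype(
    proportions: pd.DataFrame,
    treatment_col: str = "treatment",
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of each cell type's proportion across treatments.

    ``proportions`` is the output of :func:`celltype_proportions` (rows
    indexed by treatment, replicate). Every treatment needs at least 2
    replicates. Degenerate input with identical values in every group returns
    F = 0, p = 1.
    """
    treatments = proportions.index.get_level_values(treatment_col)
    uniq = sorted(set(treatments))
    if len(uniq) < 2:
        raise ValueError("need at least 2 treatments")
    for t in uniq:
        if (treatments == t).sum() < 2:
            raise ValueError(f"treatment {t!r} has fewer than 2 replicates")
    rows = []
    for ct in proportions.columns:
        groups = [proportions.loc[treatments == t, ct].to_numpy() for t in uniq]
        flat = np.concatenate(groups)
        if np.ptp(flat) == 0:
            f_stat, p = 0.0, 1.0
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                f_stat, p = f_oneway(*groups)
            if not np.isfinite(p):
                f_stat, p = (np.inf, 0.0) if _ss_between(groups) > 0 else (0.0, 1.0)
        rows.append({"cell_type": ct, "F": float(f_stat), "p_value": float(p)})
    return pd.DataFrame(rows).set_index("cell_type")


def _ss_between(groups: list[np.ndarray]) -> float:
    grand = np.concatenate(groups).mean()
    return float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
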