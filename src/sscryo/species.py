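"""Barnyard-style species demultiplexing by the dual-genome UMI-margin rule.

Each barcode is aligned against both the rat and the mouse reference; a cell
is called for a species only when its total UMI count on that reference is
strictly more than 5% (the margin) higher than on the other reference, and
``unknown`` otherwise. Totals are summed over every gene of each reference,
mitochondrial genes included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DualSpeciesCounts

__all__ = [
    "DEFAULT_MARGIN",
    "SpeciesCall",
    "assign_species",
    "assign_all",
    "evaluate_assignment",
]

DEFAULT_MARGIN = 0.05

CALLS = ("rat", "mouse", "unknown")


@dataclass(frozen=True)
class SpeciesCall:
    barcode: str
    rat_umi_total: int
    mouse_umi_total: int
    call: str
    margin: float = DEFAULT_MARGIN


def assign_species(
    rat_umi: int, mouse_umi: int, margin: float = DEFAULT_MARGIN
) -> str:
    """Call one cell rat/mouse/unknown from its two reference UMI totals.

    ``rat`` iff rat_umi > (1 + margin) * mouse_umi, symmetrically for
    ``mouse``; anything else (including ties and the all-zero cell) is
    ``unknown``. The comparison is strict, so a count exactly 5% above the
    other reference is still unknown.
    """
    if rat_umi < 0 or mouse_umi < 0:
        raise ValueError("UMI totals must be nonnegative")
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    if rat_umi > (1.0 + margin) * mouse_umi:
        return "rat"
    if mouse_umi > (1.0 + margin) * rat_umi:
        return "mouse"
    return "unknown"


def assign_all(
    counts: DualSpeciesCounts, margin: float = DEFAULT_MARGIN
) -> pd.DataFrame:
    """Vectorized margin-rule calls for every barcode.

    Returns a frame indexed by barcode with columns ``rat_umi``,
    ``mouse_umi`` and ``call``.
    """
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    totals = counts.species_totals()
    rat = totals["rat_umi"].to_numpy(dtype=np.float64)
    mouse = totals["mouse_umi"].to_numpy(dtype=np.float64)
    call = np.where(
        rat > (1.0 + margin) * mouse,
        "rat",
        np.where(mouse > (1.0 + margin) * rat, "mouse", "unknown"),
    )
    return pd.DataFrame(
        {
            "rat_umi": totals["rat_umi"],
            "mouse_umi": totals["mouse_umi"],
            "call": call,
        },
        index=totals.index,
    )


def evaluate_assignment(
    calls: pd.DataFrame, truth: pd.Series | pd.DataFrame
) -> dict:
    """Score species calls against ground truth.

    ``accuracy`` is the fraction of *all* cells whose call equals the true
    species (an unknown call therefore counts against accuracy), matching the
    pure-sample validation design. Also returns the call x truth confusion
    table and the unknown rate.
    """
    true_species = truth["species"] if isinstance(truth, pd.DataFrame) else truth
    missing = calls.index.difference(true_species.index)
    if len(missing):
        raise ValueError(
            f"truth missing for {len(missing)} barcodes, e.g. {missing[0]!r}"
        )
    true_aligned = true_species.loc[calls.index]
    correct = (calls["call"] == true_aligned).sum()
    n = len(calls)
    confusion = (
        pd.crosstab(calls["call"], true_aligned)
        .reindex(index=list(CALLS), columns=["rat", "mouse"], fill_value=0)
        .rename_axis(index="call", columns="truth")
    )
    assert int(confusion.to_numpy().sum()) == n
    return {
        "n_cells": int(n),
        "accuracy": float(correct / n) if n else float("nan"),
        "unknown_rate": float((calls["call"] == "unknown").mean()) if n else float("nan"),
        "confusion": confusion,
    }
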