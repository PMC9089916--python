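"""Ideal cell-number arithmetic of the spermatogenic lineage.

One spermatogonial stem cell founds a clone that expands through mitotic
doublings (progenitor spermatogonia, then differentiating spermatogonia A1-A4,
intermediate and type B), divides once more into preleptotene spermatocytes,
and finally yields four haploid spermatids per spermatocyte through the two
meiotic divisions. With the canonical division counts this gives 512 type B
spermatogonia (the ~500-fold mitotic amplification) and 4,096 spermatids per
stem cell. Real clones lose cells at every step, so these are upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .markers import STAGES

__all__ = ["LineageModel", "ideal_lineage_counts"]


@dataclass(frozen=True)
class LineageModel:
    """Division structure of the germ-cell lineage.

    Parameters
    ----------
    doublings_to_B
        Total mitotic doublings from one stem cell to type B spermatogonia.
    progenitor_doublings
        How many of those doublings occur in the (undifferentiated)
        progenitor compartment; the remainder are differentiating divisions.
    doublings_B_to_prelep
        Doublings from type B to preleptotene spermatocytes.
    meiotic_yield
        Haploid spermatids produced per spermatocyte entering meiosis.
    """

    stage_names: tuple[str, ...] = STAGES
    doublings_to_B: int = 9
    progenitor_doublings: int = 3
    doublings_B_to_prelep: int = 1
    meiotic_yield: int = 4

    def __post_init__(self) -> None:
        for name in ("doublings_to_B", "progenitor_doublings",
                     "doublings_B_to_prelep"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if not isinstance(self.meiotic_yield, int) or self.meiotic_yield < 1:
            raise ValueError(
                f"meiotic_yield must be a positive integer, got {self.meiotic_yield!r}"
            )
        if self.progenitor_doublings > self.doublings_to_B:
            raise ValueError(
                "progenitor_doublings cannot exceed doublings_to_B "
                f"({self.progenitor_doublings} > {self.doublings_to_B})"
            )
        if len(self.stage_names) != 7:
            raise ValueError("expected exactly 7 lineage stages")

    @property
    def spermatid_yield(self) -> int:
        """Ideal spermatids per stem cell: 2^(total premeiotic doublings) x meiotic yield."""
        return (
            2 ** (self.doublings_to_B + self.doublings_B_to_prelep)
            * self.meiotic_yield
        )


def ideal_lineage_counts(model: LineageModel | None = None) -> dict[str, int]:
    """Ideal number of cells at each stage descending from one stem cell.

    Returns a mapping over the seven canonical stages. The differentiating
    spermatogonia count is reported at the end of that compartment (type B);
    spermatocyte counts are constant through meiotic prophase, and both
    spermatid stages carry the full meiotic yield.

    >>> ideal_lineage_counts()["elongating spermatid"]
    4096
    """
    model = LineageModel() if model is None else model
    b_count = 2 ** model.doublings_to_B
    prelep = b_count * 2 ** model.doublings_B_to_prelep
    spermatids = prelep * model.meiotic_yield
    assert spermatids == model.spermatid_yield
    counts = {
        model.stage_names[0]: 1,
        model.stage_names[1]: 2 ** model.progenitor_doublings,
        model.stage_names[2]: b_count,
        model.stage_names[3]: prelep,
        model.stage_names[4]: prelep,
        model.stage_names[5]: spermatids,
        model.stage_names[6]: spermatids,
    }
    return counts
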