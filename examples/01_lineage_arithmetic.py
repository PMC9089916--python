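"""Ideal cell-number arithmetic of the spermatogenic lineage.

One stem cell expands through 9 mitotic doublings to type B spermatogonia,
one more doubling into meiosis, and yields 4 spermatids per spermatocyte.
"""

from sscryo import LineageModel, ideal_lineage_counts

counts = ideal_lineage_counts(LineageModel())
for stage, n in counts.items():
    print(f"{stage:32s} {n:6d}")

print(
    f"\nOne stem cell can ideally found {counts['elongating spermatid']:,} "
    "spermatids; the ~500-fold premeiotic amplification is the "
    f"{counts['differentiating spermatogonia']}-cell type-B compartment."
)
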