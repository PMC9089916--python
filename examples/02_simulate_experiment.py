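"""Simulate a dual-species transplant experiment and inspect the ground truth.

The `transplanted_unselected` preset plants the long-frozen phenotype: more
stem cells, fewer elongating spermatids, and suppressed transition-protein /
protamine genes in round spermatids.
"""

from sscryo import preset, simulate_experiment

cfg = preset("transplanted_unselected", seed=0, cells_per_replicate=200)
counts, truth = simulate_experiment(cfg)

print(f"cells: {counts.n_cells}, rat genes: {len(counts.rat_genes)}, "
      f"mouse genes: {len(counts.mouse_genes)}")
print("\ncells per arm:")
print(truth.cells["treatment"].value_counts().to_string())
print("\nplanted expression effects (log2 fold change vs baseline arm):")
print(truth.fold_changes.to_string(index=False))
print(
    "\nNegative log2fc entries are the planted round-spermatid suppression "
    "of chromatin-remodeling genes in the frozen arms."
)
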