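# Methods

This note documents the models, parameters, numerical choices, and known
limitations of `sscryo`. Everything stated here is computed by the package's
tests or examples; nothing is an external empirical claim.

## Lineage model

`LineageModel` encodes the division arithmetic of rat spermatogenesis: a
stem cell undergoes `doublings_to_B = 9` mitotic doublings to type B
spermatogonia (of which `progenitor_doublings = 3` are in the
undifferentiated progenitor compartment), one further doubling into
preleptotene spermatocytes (`doublings_B_to_prelep = 1`), and each
spermatocyte yields `meiotic_yield = 4` haploid spermatids. The implied
ideal counts are 1 SSC → 512 type B (the ~500-fold premeiotic
amplification) → 1,024 spermatocytes → 4,096 spermatids. These are upper
bounds; real clones lose cells at every step. The `progenitor_doublings`
split is our addition so that all seven stages get an ideal count; it does
not affect the terminal yield invariant
`2^(doublings_to_B + doublings_B_to_prelep) × meiotic_yield`.

## Synthetic-data generator

The generator emulates the count-matrix entry point of a barnyard
(dual-reference) droplet experiment. Per cell:

- **Library size** `L ~ Lognormal(mean = 3,000 UMIs, sigma = 0.35)`. The
  sequencing depth the design targets is reads, not UMIs, so the UMI default
  is set well below read depth and is configurable.
- **Counts** are gamma-Poisson (negative binomial) per gene: rate
  `L · w_g · Gamma(1/φ, φ)` with shared dispersion `φ = 0.15`, the standard
  droplet noise model.
- **Mitochondrial fraction** `m ~ Beta(1.5, 18)` (mean ≈ 7.7%, ~5% of cells
  above the 20% QC cutoff), spent on 13 mitochondrially encoded genes.
- **Ambient contamination**: a fraction `r = 0.01` of each cell's library is
  drawn (Poisson) from the *other* species' population-average expression
  profile; the cell's own species keeps `(1 − r)·L` in expectation. Doublets
  are not modeled.

Expression profiles per stage combine, on top of a lognormal baseline:

- the 17 marker-panel genes at 40× in their own stage (the transition
  proteins/protamines additionally at 10× in round spermatids, since they
  switch on before elongation);
- two opposing 30-gene programs ramping geometrically 16× down/up across the
  seven stages — the monotone axis a linear pseudotime should recover. The
  40×/16× magnitudes are conservative relative to the >100-fold swings of
  genes like *Prm1* across real spermatogenesis;
- a 40-gene stage-identity program per stage (6× in its own stage, ~1.8× in
  the neighbors). Real adjacent germ-cell stages differ transcriptome-wide,
  not in a handful of markers; without these broad programs no unsupervised
  clustering could separate stages and cluster-based typing would be
  meaningless;
- inducible programs: a 20-gene cell-stress program and the 38-gene
  proapoptotic program (3× in cells flagged apoptotic, default 5% per arm).

Stage weights for "unselected" sampling are late-stage heavy (SSC 2% …
round spermatid 33%), a qualitative reflection of the lineage amplification;
no quantitative stage census of the rat testis is available, so these are
configuration, not claims. EpCAM selection is modeled as multiplying the
weights of the three premeiotic stages (default factor 5 in the
`thawed_epcam` preset). Replicate-to-replicate composition noise is
multiplicative lognormal (`sigma = 0.15`) on the stage weights; at a
proportion of ~0.12 this gives a within-arm SD of ~0.02.

Treatment presets plant the directional effects of the study design:

- `thawed_epcam`: stress program up in SSCs, 1.5× (short-frozen) and 2.25×
  (long-frozen). The short-frozen magnitude uses the 1.5 default for
  unprinted effects; long-frozen is graded above it.
- `transplanted_unselected`: in the long-frozen arm, stage-weight shifts of
  +0.10 (SSC), +0.04 (differentiating spermatogonia), −0.14 (elongating
  spermatid), and round-spermatid suppression of Prm1 (1/2.0), Tnp1 (1/2.1)
  and Tnp2 (1/1.5) relative to transplanted fresh, with the smaller printed
  short-frozen ratios planted in that arm.
- `pure_species`: one pure-rat and one pure-mouse sample of 10,000 cells,
  used for classifier validation.

Every planted (arm, stage, gene) fold change is returned in the ground-truth
table as its ideal log2 value. Because stage profiles are renormalized after
planting, the realized compositional fold differs from the ideal one by
< 2% for genes holding a small share of the library; the recovery tolerance
(±0.3 log2 units) absorbs this.

What the generator does **not** emulate: batch effects and integration,
doublets and barcode errors, somatic cell types, cell-cycle structure,
read-level artifacts, and gene–gene correlation beyond the shared program
structure. Passing tests therefore demonstrate correctness of the
statistical machinery under a faithful-but-idealized noise model, not
robustness to every artifact of real droplet data.

## Species assignment

Calls operate on UMI totals summed over all genes of each reference,
mitochondrial genes included. The margin comparison is strict
(`n_rat > (1+m)·n_mouse`), so totals exactly 5% apart stay unknown; equality
(including the all-zero cell) is unknown. Accuracy is measured over all
cells, so unknown calls count against it — the conservative reading of a
pure-sample validation.

## QC, normalization, typing, pseudotime

- `pct_mito` of a zero-total cell is defined as 0; such a cell is removed by
  the UMI floor anyway. The mito rule removes strictly above 20%; the
  gene/UMI floors (defaults 200 genes, 500 UMIs — "low quality" is otherwise
  unquantified) keep cells at the boundary. Filtering is idempotent.
- Normalization is counts-per-million (not the per-10k convention), natural
  log, pseudocount 1. Zero patterns are preserved exactly.
- Clustering is k-means on the top 20 PCs of log-CPM. The default k = 12
  deliberately over-clusters relative to the seven panels: each cluster is
  labeled by its best-scoring panel and several clusters collapse onto one
  type. With k equal to the number of panels, k-means tends to merge the
  small premeiotic stages with their neighbors, which caps typing accuracy
  well below the ≥ 90% the package commits to; over-clustering removes that
  failure mode while leaving the typing contract (labels only) unchanged.
  Panel-score ties are broken by canonical stage order, earliest first.
- Pseudotime is deliberately simple — PC1 of log-CPM rescaled to [0, 1] and
  oriented so the top decile of start-gene (*Etv5*) expression averages
  below 0.5. It is a stand-in for graph-based trajectory inference, adequate
  because the germ-cell lineage is a single unbranched path; it is not
  suitable for branched processes.

## Pseudobulk statistics

Pseudobulk rows average *normalized* (log-CPM) expression over one
replicate's cells of one type — matching "average expression per cell"
semantics — with raw-count aggregation available but not default. The
distance metric is Euclidean (configurable); no metric is canonical here and
Euclidean-on-log is the common choice. The PERMANOVA pseudo-F follows
Anderson's distance-only formulation; the permutation p uses the add-one
convention so p is never 0, and an exhaustive mode enumerates all distinct
labelings for small designs. A consequence worth knowing: a 3-vs-3 design
has 20 labelings of which the observed partition and its mirror always tie
the observed F, so the smallest attainable p is exactly 0.1 — a well-powered
3+3 test saturates that floor rather than passing below it.

## Differential expression

Wilcoxon rank-sum on CPM values pooled across replicates (tie-corrected
normal approximation with continuity correction; the exact distribution for
tie-free groups of ≤ 7 cells). Genes identical across both groups get
p = 1. Fold changes are `log2((mean_A + 1)/(mean_B + 1))` on CPM-scale group
means; the pseudocount stabilizes low-expression genes at the cost of
shrinking their fold estimates. Multiple testing is Benjamini–Hochberg (the
procedure behind "FDR" is not otherwise specified); both significance
cutoffs are inclusive (|log2FC| ≥ log2 1.5, p_adj ≤ 0.05). Pooling cells
across replicates treats cells as exchangeable within arms
(pseudoreplication is not modeled — a known limitation shared with the
standard single-cell DE workflow).

## Module scores and proportions

The module score implements the published binned-control definition: genes
are ranked by mean expression over all cells into 25 equal-frequency bins;
for each program gene, up to 100 control genes are sampled (without
replacement) from its bin — the whole bin if smaller — and the score is
mean(program) − mean(control pool). Hence a program equal to the whole gene
universe scores exactly 0, and adding a constant to a cell's profile cancels.
The score is deterministic under its seed but the control draw is genuinely
stochastic across seeds. With only 38 sparse genes the per-cell score
distribution is wide, so the fixed 0.1 cutoff flags a substantial background
fraction in synthetic data; since the cutoff is arbitrary by construction,
the meaningful statistic is the *comparison* of flagged fractions across
arms, which is null by design here.

ANOVA on proportions is one-way, fixed-effects, on untransformed fractions
(arcsine-sqrt available as an option), run separately per cell type with no
cross-type correction, mirroring per-type reporting. Degenerate inputs
(identical values everywhere) return F = 0, p = 1.

## Problem sizes and determinism

Default presets use 3 replicates × 400 cells per arm and 1,000 genes per
species; the classifier validation uses 2 × 10,000 cells. These sizes give
stable estimates for every statistic the package reports while keeping any
simulation re-runnable in seconds on a laptop. All randomness flows from a
single integer seed; pipeline stages draw from independently derived child
seeds, so disabling one stage never perturbs another and identical
configurations produce byte-identical reports.
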