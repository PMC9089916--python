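"""End-to-end orchestration: simulate (or load) -> species assignment -> QC ->
typing -> pseudobulk PERMANOVA -> differential expression -> module scores and
cell-type proportions.

Mirrors the two-arm analysis design of the underlying experiment: samples are
demultiplexed against both genomes, only rat-called cells continue, and every
replicate-level statistic is computed per treatment arm. The whole run is
deterministic under ``PipelineConfig.seed``; each stage draws its randomness
from an independently spawned child seed so that disabling one stage never
perturbs another.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import celltypes, de, qc, scoring, species
from . import pseudobulk as pb
from .io import write_config_yaml, write_dual_counts
from .markers import MARKER_PANELS, MITO_GENES
from .simulate import (
    DualSpeciesCounts,
    GeneratorConfig,
    GroundTruth,
    preset,
    simulate_experiment,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_DE_CELLTYPES = ("round spermatid", "elongating spermatid")


@dataclass
class PipelineConfig:
    """Thresholds and stage toggles of a full analysis run."""

    preset_name: str = "transplanted_unselected"
    generator: GeneratorConfig | None = None
    margin: float = species.DEFAULT_MARGIN
    mito_max: float = qc.MITO_MAX_PCT
    min_genes: int = qc.MIN_GENES
    min_umi: int = qc.MIN_UMI
    n_clusters: int | None = None
    permanova_celltype: str = "SSC"
    pooling: dict[str, str] | None = None
    n_permutations: int = 1000
    de_comparisons: list[tuple[str, str, str]] | None = None
    fc_min: float = de.FC_MIN
    padj_max: float = de.PADJ_MAX
    module_cutoff: float = scoring.APOPTOSIS_CUTOFF
    enable_pseudobulk: bool = True
    enable_de: bool = True
    enable_scoring: bool = True
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if self.margin < 0 or self.mito_max < 0:
            raise ValueError("margin and mito_max must be nonnegative")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if not 0 < self.padj_max <= 1:
            raise ValueError("padj_max must lie in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def _auto_pooling(treatments) -> dict[str, str]:
    """Pool every *frozen* arm into one group, as in the fresh-vs-frozen test."""
    return {t: ("frozen" if t.endswith("frozen") else t) for t in treatments}


def _child_seed(root_seed: int, index: int) -> int:
    """Independent per-stage seed; stable no matter which stages run."""
    child = np.random.SeedSequence(entropy=root_seed, spawn_key=(index,))
    return int(child.generate_state(1)[0] & 0x7FFFFFFF)


def run_pipeline(
    config: PipelineConfig,
    counts: DualSpeciesCounts | None = None,
    truth: GroundTruth | None = None,
) -> dict:
    """Run every enabled stage in order and return the machine-readable report.

    When ``counts`` is not supplied, the configured generator preset is
    simulated first. ``truth`` (when available) contributes the species
    ground truth for classifier evaluation and the treatment/replicate sample
    sheet; with external counts, ``truth.cells`` may carry only
    ``treatment``/``replicate`` columns.
    """
    config.validate()
    if config.outdir:
        Path(config.outdir).mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    report: dict = {"config": _config_echo(config), "stages": []}

    def stage_done(name: str) -> None:
        report["stages"].append(name)
        logger.info("[%s] done at %.2fs", name, time.perf_counter() - t0)

    # --- simulate -----------------------------------------------------------
    if counts is None:
        gen = config.generator or preset(
            config.preset_name, seed=_child_seed(config.seed, 0)
        )
        counts, truth = simulate_experiment(gen)
        report["config"]["generator"] = gen.to_dict()
        stage_done("simulate")
    if truth is None or "treatment" not in truth.cells.columns:
        raise ValueError("pipeline requires a sample sheet (treatment/replicate)")

    # --- species assignment -------------------------------------------------
    calls = species.assign_all(counts, margin=config.margin)
    sec: dict = {
        "margin": config.margin,
        "n_cells": int(len(calls)),
        "call_counts": calls["call"].value_counts().to_dict(),
    }
    if "species" in truth.cells.columns:
        ev = species.evaluate_assignment(calls, truth.cells["species"])
        sec.update(
            accuracy=ev["accuracy"],
            unknown_rate=ev["unknown_rate"],
            confusion={
                str(k): v for k, v in ev["confusion"].to_dict(orient="index").items()
            },
        )
    report["species"] = sec
    stage_done("species")

    # --- QC on rat-called cells --------------------------------------------
    rat_mask = (calls["call"] == "rat").to_numpy()
    X = counts.rat[np.flatnonzero(rat_mask)]
    obs = truth.cells.loc[counts.barcodes[rat_mask]].copy()
    genes = counts.rat_genes
    metrics = qc.qc_metrics(X, genes, obs.index, list(MITO_GENES))
    keep = qc.filter_cells(
        metrics,
        mito_max=config.mito_max,
        min_genes=config.min_genes,
        min_umi=config.min_umi,
    )
    report["qc"] = {
        "n_rat_cells": int(rat_mask.sum()),
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "median_genes": float(metrics["n_genes"].median()),
        "median_umi": float(metrics["n_umi"].median()),
        "median_pct_mito": float(metrics["pct_mito"].median()),
    }
    X = X[np.flatnonzero(keep.to_numpy())]
    obs = obs.loc[keep[keep].index]
    obs = obs.join(metrics.loc[obs.index])
    stage_done("qc")

    # --- normalization, clustering, typing, pseudotime -----------------------
    X_norm = qc.normalize_cpm_log(X)
    clusters = celltypes.cluster_cells(
        X_norm, k=config.n_clusters, seed=_child_seed(config.seed, 1)
    )
    scores = celltypes.score_marker_panels(X_norm, genes, MARKER_PANELS)
    scores.index = obs.index
    obs["cluster"] = clusters
    obs["cell_type"] = celltypes.annotate_cells(clusters, scores).to_numpy()
    obs["pseudotime"] = celltypes.linear_pseudotime(X_norm, genes)
    type_counts = obs["cell_type"].value_counts().to_dict()
    sec = {"n_clusters": int(len(np.unique(clusters))), "type_counts": type_counts}
    if "stage" in obs.columns:
        sec["annotation_accuracy"] = float((obs["cell_type"] == obs["stage"]).mean())
    report["cell_types"] = sec
    stage_done("typing")

    # --- pseudobulk PCA + PERMANOVA ------------------------------------------
    if config.enable_pseudobulk:
        pbm = pb.pseudobulk_mean(X_norm, genes, obs, config.permanova_celltype)
        sec = {"cell_type": config.permanova_celltype, "n_rows": int(len(pbm))}
        pooling = config.pooling or _auto_pooling(obs["treatment"].unique())
        if len(pbm) >= 4:
            groups = pb.pooled_group_design(pbm["treatment"], pooling)
            coords, var_pct = pb.pca(pbm)
            dist = pb.distance_matrix(pbm)
            res = pb.permanova(
                dist,
                groups,
                n_permutations=config.n_permutations,
                seed=_child_seed(config.seed, 2),
            )
            sec.update(
                pooling=pooling,
                group_sizes=res.group_sizes,
                pseudo_F=res.pseudo_F,
                p_value=res.p_value,
                n_permutations=res.n_permutations,
                pca_variance_pct=[float(v) for v in var_pct[:5]],
            )
        else:
            sec["skipped"] = "fewer than 4 pseudobulk rows"
        report["permanova"] = sec
        stage_done("pseudobulk")

    # --- differential expression ---------------------------------------------
    if config.enable_de:
        treatments = list(dict.fromkeys(obs["treatment"]))
        comparisons = config.de_comparisons or [
            (treatments[0], treatments[-1], ct)
            for ct in DEFAULT_DE_CELLTYPES
            if ct in type_counts
        ]
        de_sec = []
        deg_sets: dict[str, set] = {}
        for group_a, group_b, cell_type in comparisons:
            table = de.wilcoxon_de(
                X,
                genes,
                obs,
                group_a,
                group_b,
                cell_type=cell_type,
                fc_min=config.fc_min,
                padj_max=config.padj_max,
            )
            sig = de.apply_deg_cutoffs(table, config.fc_min, config.padj_max)
            key = f"{group_a}_vs_{group_b}@{cell_type}"
            deg_sets[key] = sig
            top = table.loc[sorted(sig)] if sig else table.iloc[:0]
            de_sec.append(
                {
                    "comparison": key,
                    "n_significant": len(sig),
                    "significant_genes": {
                        g: float(table.loc[g, "log2_fold_change"]) for g in sorted(sig)
                    },
                }
            )
            if config.outdir:
                table.to_csv(
                    Path(config.outdir) / f"deg_{key.replace(' ', '-')}.tsv",
                    sep="\t",
                )
            del top
        sec = {"comparisons": de_sec}
        if len(deg_sets) >= 2:
            sec["overlap"] = de.overlap_sets(deg_sets)
        report["de"] = sec
        stage_done("de")

    # --- module scores and proportions ---------------------------------------
    if config.enable_scoring:
        ms = scoring.module_score(
            X_norm,
            genes,
            scoring.PROAPOPTOTIC_PROGRAM,
            seed=_child_seed(config.seed, 3),
        )
        flags, fractions = scoring.classify_apoptotic(
            ms, obs, cutoff=config.module_cutoff
        )
        obs["apoptosis_score"] = ms
        obs["apoptotic_call"] = flags
        props = scoring.celltype_proportions(obs)
        anova = scoring.anova_per_celltype(props)
        mean_props = props.groupby(level="treatment", observed=True).mean()
        report["scoring"] = {
            "program": scoring.PROAPOPTOTIC_PROGRAM.name,
            "cutoff": config.module_cutoff,
            "apoptotic_rate": float(np.mean(flags)),
            "per_type_fraction": {
                f"{r}|{ct}": float(v)
                for r, ct, v in fractions.itertuples(index=False)
            },
        }
        report["proportions"] = {
            "mean_by_treatment": {
                t: {ct: float(v) for ct, v in row.items()}
                for t, row in mean_props.iterrows()
            },
            "anova": {
                ct: {"F": float(r["F"]), "p_value": float(r["p_value"])}
                for ct, r in anova.iterrows()
            },
        }
        stage_done("scoring")

    report["elapsed_seconds"] = round(time.perf_counter() - t0, 3)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_dual_counts(counts, outdir / "counts")
        obs.to_csv(outdir / "annotations.tsv", sep="\t")
        write_config_yaml(report["config"], outdir / "config_echo.yaml")
        with open(outdir / "report.json", "w") as fh:
            json.dump(_strip_volatile(report), fh, indent=2, default=_jsonify)
    return report


def _config_echo(config: PipelineConfig) -> dict:
    d = asdict(config)
    if config.generator is not None:
        d["generator"] = config.generator.to_dict()
    return d


def _strip_volatile(report: dict) -> dict:
    out = dict(report)
    out.pop("elapsed_seconds", None)
    return out


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
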