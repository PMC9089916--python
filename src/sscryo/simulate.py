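"""Seeded dual-species droplet scRNA-seq count simulator.

Emulates the count-matrix entry point of a rat-into-mouse germ-cell
xenotransplant experiment: every cell is a rat or mouse germ cell drawn from
one of seven lineage stages, sequenced against *both* reference gene
universes. A cell's own-species genes receive gamma-Poisson (negative
binomial) UMI counts from a stage-specific expression profile; the
wrong-species genes receive only ambient "soup" counts at a configurable
fraction of the cell's library. Treatment arms can plant expression fold
changes per (stage, gene), shift stage proportions, and raise per-stage
apoptotic fractions, and every planted effect is returned as ground truth so
downstream estimators can be scored against it.

Stage expression profiles combine a lognormal baseline with three kinds of
structure: stage-restricted marker panels (strongly elevated in their own
stage, with the spermiogenesis transition-protein/protamine panel also
expressed at intermediate level in round spermatids, as in vivo), a pair of
opposing gene programs ramping monotonically down/up along the lineage (the
axis a linear pseudotime should recover), and inducible stress/apoptosis
programs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .markers import (
    STAGES,
    EARLY_STAGES,
    MARKER_PANELS,
    PROAPOPTOTIC_GENES,
    STRESS_GENES,
    MITO_GENES,
    all_panel_genes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ArmEffects",
    "GeneratorConfig",
    "GeneUniverse",
    "DualSpeciesCounts",
    "GroundTruth",
    "build_gene_universe",
    "simulate_experiment",
    "apply_epcam_enrichment",
    "preset",
    "PRESET_NAMES",
]

N_PROGRAM_GENES = 30
N_STAGE_PROGRAM_GENES = 40
MOUSE_PREFIX = "mm-"

#: Default unselected-sample stage weights: qualitatively late-stage heavy,
#: reflecting the mitotic/meiotic amplification of the lineage. These are
#: configuration, not measured proportions.
DEFAULT_STAGE_PROPORTIONS: dict[str, float] = {
    "SSC": 0.02,
    "progenitor": 0.03,
    "differentiating spermatogonia": 0.07,
    "early spermatocyte": 0.12,
    "late spermatocyte": 0.16,
    "round spermatid": 0.33,
    "elongating spermatid": 0.27,
}


@dataclass
class ArmEffects:
    """Planted treatment effects for one arm, relative to the baseline profile.

    ``expression_folds`` maps stage -> {gene: fold}; fold < 1 is suppression.
    ``stage_shift`` adds to the arm's stage proportions (renormalized).
    ``species_fraction_rat`` is the fraction of the arm's cells that are rat.
    """

    expression_folds: dict[str, dict[str, float]] = field(default_factory=dict)
    stage_shift: dict[str, float] = field(default_factory=dict)
    apoptotic_fraction: float | None = None
    species_fraction_rat: float = 1.0

    def validate(self) -> None:
        for stage, folds in self.expression_folds.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage in expression_folds: {stage!r}")
            for gene, f in folds.items():
                if not f > 0:
                    raise ValueError(f"fold for {gene!r} must be > 0, got {f}")
        for stage in self.stage_shift:
            if stage not in STAGES:
                raise ValueError(f"unknown stage in stage_shift: {stage!r}")
        if self.apoptotic_fraction is not None and not (
            0 <= self.apoptotic_fraction < 1
        ):
            raise ValueError("apoptotic_fraction must lie in [0, 1)")
        if not 0 <= self.species_fraction_rat <= 1:
            raise ValueError("species_fraction_rat must lie in [0, 1]")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic experiment; see module docstring."""

    n_genes_per_species: int = 1000
    marker_panels: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(MARKER_PANELS)
    )
    treatments: tuple[str, ...] = ("fresh",)
    replicates_per_arm: int = 3
    cells_per_replicate: int = 400
    mean_umis_per_cell: float = 3000.0
    libsize_sigma: float = 0.35
    dispersion: float = 0.15
    ambient_cross_species_rate: float = 0.01
    mito_beta: tuple[float, float] = (1.5, 18.0)
    epcam_enrichment_factor: float = 1.0
    stage_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_PROPORTIONS)
    )
    proportion_noise_sigma: float = 0.15
    marker_fold: float = 40.0
    program_fold: float = 16.0
    stage_program_fold: float = 6.0
    spillover_fold: float = 10.0
    apoptotic_fraction: float = 0.05
    apoptosis_induction: float = 3.0
    effects: dict[str, ArmEffects] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.cells_per_replicate < 1 or self.replicates_per_arm < 1:
            raise ValueError("need at least one cell and one replicate per arm")
        if not self.treatments:
            raise ValueError("need at least one treatment arm")
        if self.mean_umis_per_cell <= 0:
            raise ValueError("mean_umis_per_cell must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if not 0 <= self.ambient_cross_species_rate < 1:
            raise ValueError("ambient_cross_species_rate must lie in [0, 1)")
        if self.epcam_enrichment_factor < 1:
            raise ValueError("epcam_enrichment_factor must be >= 1")
        if min(self.mito_beta) <= 0:
            raise ValueError("mito_beta parameters must be positive")
        if not 0 <= self.apoptotic_fraction < 1:
            raise ValueError("apoptotic_fraction must lie in [0, 1)")
        if set(self.stage_proportions) != set(STAGES):
            raise ValueError("stage_proportions must cover exactly the 7 stages")
        if any(v < 0 for v in self.stage_proportions.values()):
            raise ValueError("stage proportions must be nonnegative")
        for panel, genes in self.marker_panels.items():
            if not genes:
                raise ValueError(f"marker panel {panel!r} is empty")
        for arm, eff in self.effects.items():
            if arm not in self.treatments:
                raise ValueError(f"effects given for unknown arm {arm!r}")
            eff.validate()
        # universe capacity is checked in build_gene_universe

    def to_dict(self) -> dict:
        d = asdict(self)
        d["treatments"] = list(self.treatments)
        d["marker_panels"] = {k: list(v) for k, v in self.marker_panels.items()}
        d["mito_beta"] = list(self.mito_beta)
        return d


@dataclass
class GeneUniverse:
    """Two disjoint species gene namespaces with role annotations.

    ``table`` has one row per gene with columns ``gene``, ``species``
    (rat/mouse), ``role`` (marker / apoptosis / stress / early_program /
    late_program / mito / filler) and ``marker_stage`` (for markers).
    """

    table: pd.DataFrame

    def genes(self, species: str) -> pd.Index:
        sub = self.table[self.table["species"] == species]
        return pd.Index(sub["gene"].to_numpy(), name="gene")

    def mito_genes(self, species: str) -> list[str]:
        sub = self.table[
            (self.table["species"] == species) & (self.table["role"] == "mito")
        ]
        return list(sub["gene"])

    def role_genes(self, species: str, role: str) -> list[str]:
        sub = self.table[
            (self.table["species"] == species) & (self.table["role"] == role)
        ]
        return list(sub["gene"])


@dataclass
class DualSpeciesCounts:
    """Paired cells x genes UMI matrices over shared barcodes."""

    rat: sp.csr_matrix
    mouse: sp.csr_matrix
    rat_genes: pd.Index
    mouse_genes: pd.Index
    barcodes: pd.Index

    def __post_init__(self) -> None:
        if self.rat.shape[0] != self.mouse.shape[0]:
            raise ValueError("rat and mouse matrices must share barcodes")
        if self.rat.shape != (len(self.barcodes), len(self.rat_genes)):
            raise ValueError("rat matrix shape inconsistent with labels")
        if self.mouse.shape != (len(self.barcodes), len(self.mouse_genes)):
            raise ValueError("mouse matrix shape inconsistent with labels")

    @property
    def n_cells(self) -> int:
        return self.rat.shape[0]

    def species_totals(self) -> pd.DataFrame:
        """Per-barcode total UMI counts against each reference."""
        return pd.DataFrame(
            {
                "rat_umi": np.asarray(self.rat.sum(axis=1)).ravel().astype(np.int64),
                "mouse_umi": np.asarray(self.mouse.sum(axis=1)).ravel().astype(np.int64),
            },
            index=self.barcodes,
        )

    def to_anndata(self, species: str = "rat"):
        """View one species' matrix as an AnnData (cells x genes)."""
        import anndata as ad

        X = self.rat if species == "rat" else self.mouse
        genes = self.rat_genes if species == "rat" else self.mouse_genes
        return ad.AnnData(
            X=X.copy(),
            obs=pd.DataFrame(index=self.barcodes.copy()),
            var=pd.DataFrame(index=genes.copy()),
        )


@dataclass
class GroundTruth:
    """Per-cell truth and the planted per-gene fold-change table."""

    cells: pd.DataFrame
    fold_changes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.cells.index.has_duplicates:
            raise ValueError("one truth record per barcode required")


def _rat_gene_roster(config: GeneratorConfig) -> pd.DataFrame:
    panel = all_panel_genes(config.marker_panels)
    stage_of = {
        g: stage for stage, genes in config.marker_panels.items() for g in genes
    }
    rows: list[tuple[str, str, str]] = []
    for g in panel:
        rows.append((g, "marker", stage_of[g]))
    for g in PROAPOPTOTIC_GENES:
        rows.append((g, "apoptosis", ""))
    for g in STRESS_GENES:
        rows.append((g, "stress", ""))
    for i in range(N_PROGRAM_GENES):
        rows.append((f"early_prog_{i + 1:02d}", "early_program", ""))
    for i in range(N_PROGRAM_GENES):
        rows.append((f"late_prog_{i + 1:02d}", "late_program", ""))
    for si, stage in enumerate(STAGES):
        for i in range(N_STAGE_PROGRAM_GENES):
            rows.append((f"stage{si + 1}_prog_{i + 1:02d}", "stage_program", stage))
    for g in MITO_GENES:
        rows.append((g, "mito", ""))
    n_special = len(rows)
    if config.n_genes_per_species < n_special:
        raise ValueError(
            f"n_genes_per_species={config.n_genes_per_species} cannot hold the "
            f"{n_special} marker/program/mitochondrial genes"
        )
    n_filler = config.n_genes_per_species - n_special
    for i in range(n_filler):
        rows.append((f"Rgene{i + 1:04d}", "filler", ""))
    df = pd.DataFrame(rows, columns=["gene", "role", "marker_stage"])
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"gene namespace collision: {dup!r}")
    return df


def build_gene_universe(config: GeneratorConfig) -> GeneUniverse:
    """Construct disjoint rat/mouse gene namespaces with role flags.

    Rat genes carry bare symbols; mouse orthologs carry an ``mm-`` prefix,
    guaranteeing disjointness. Every marker-panel gene is present on the rat
    side (and mirrored on the mouse side).
    """
    rat = _rat_gene_roster(config)
    rat.insert(1, "species", "rat")
    mouse = rat.copy()
    mouse["species"] = "mouse"
    mouse["gene"] = MOUSE_PREFIX + mouse["gene"]
    table = pd.concat([rat, mouse], ignore_index=True)
    if set(rat["gene"]) & set(mouse["gene"]):
        raise ValueError("rat and mouse gene namespaces collide")
    return GeneUniverse(table=table)


# ---------------------------------------------------------------------------
# expression profiles
# ---------------------------------------------------------------------------

_BASELINE_WEIGHT = {
    "marker": 3.0,
    "early_program": 3.0,
    "late_program": 3.0,
    "stage_program": 1.5,
    "stress": 2.0,
    "apoptosis": 1.5,
}


class _SpeciesModel:
    """Stage x gene expression shares for one species (nuclear + mito)."""

    def __init__(
        self,
        roster: pd.DataFrame,
        config: GeneratorConfig,
        rng: np.random.Generator,
        apply_effects: bool,
    ):
        self.genes = pd.Index(roster["gene"].to_numpy(), name="gene")
        roles = roster["role"].to_numpy()
        self.nuclear = np.flatnonzero(roles != "mito")
        self.mito = np.flatnonzero(roles == "mito")
        nuc = roster.iloc[self.nuclear]
        nuc_roles = nuc["role"].to_numpy()

        w = np.where(
            nuc_roles == "filler",
            rng.lognormal(0.0, 1.5, size=len(nuc)),
            [_BASELINE_WEIGHT.get(r, 1.0) for r in nuc_roles],
        )
        self.mito_share = rng.lognormal(0.0, 0.5, size=len(self.mito))
        self.mito_share /= self.mito_share.sum()

        n_stages = len(STAGES)
        mult = np.ones((n_stages, len(nuc)))
        stage_idx = {s: i for i, s in enumerate(STAGES)}
        strip = (
            lambda g: g[len(MOUSE_PREFIX):] if g.startswith(MOUSE_PREFIX) else g
        )
        bare = np.array([strip(g) for g in nuc["gene"]])
        marker_stage = nuc["marker_stage"].to_numpy()
        round_i = stage_idx["round spermatid"]
        elong_i = stage_idx["elongating spermatid"]
        for j in np.flatnonzero(nuc_roles == "marker"):
            si = stage_idx[marker_stage[j]]
            mult[si, j] *= config.marker_fold
            # transition proteins/protamines begin in round spermatids
            if si == elong_i:
                mult[round_i, j] *= config.spillover_fold
        down = np.geomspace(config.program_fold, 1.0, n_stages)
        up = np.geomspace(1.0, config.program_fold, n_stages)
        mult[:, nuc_roles == "early_program"] *= down[:, None]
        mult[:, nuc_roles == "late_program"] *= up[:, None]
        # broad stage-identity programs: strongly up in their own stage,
        # mildly in the neighboring stages (transcriptomic continuity)
        for j in np.flatnonzero(nuc_roles == "stage_program"):
            si = stage_idx[marker_stage[j]]
            mult[si, j] *= config.stage_program_fold
            for nb in (si - 1, si + 1):
                if 0 <= nb < n_stages:
                    mult[nb, j] *= config.stage_program_fold ** 0.33

        self._gene_pos = {g: j for j, g in enumerate(nuc["gene"])}
        self._bare_pos = {g: j for j, g in enumerate(bare)}
        self._w = w
        self._base_mult = mult
        self._apop_cols = np.flatnonzero(nuc_roles == "apoptosis")
        self._config = config

        self.shares: dict[str, np.ndarray] = {}
        for arm in config.treatments:
            m = mult.copy()
            eff = config.effects.get(arm) if apply_effects else None
            if eff is not None:
                for stage, folds in eff.expression_folds.items():
                    si = stage_idx[stage]
                    for gene, fold in folds.items():
                        j = self._bare_pos.get(gene)
                        if j is None:
                            raise ValueError(
                                f"effect gene {gene!r} not in gene universe"
                            )
                        m[si, j] *= fold
            self.shares[arm] = self._normalize(m)

    def _normalize(self, mult: np.ndarray) -> np.ndarray:
        """(n_stages, 2, G_nuclear): axis 1 is [healthy, apoptotic]."""
        cfg = self._config
        healthy = self._w * mult
        apop = healthy.copy()
        apop[:, self._apop_cols] *= cfg.apoptosis_induction
        out = np.stack(
            [
                healthy / healthy.sum(axis=1, keepdims=True),
                apop / apop.sum(axis=1, keepdims=True),
            ],
            axis=1,
        )
        return out

    def ambient_profile(self, stage_props: np.ndarray, mean_mito: float) -> np.ndarray:
        """Population-average expression over all genes (the 'soup')."""
        base = self._normalize(self._base_mult)[:, 0, :]  # healthy, no effects
        nuclear_avg = stage_props @ base
        out = np.zeros(len(self.genes))
        out[self.nuclear] = nuclear_avg * (1.0 - mean_mito)
        out[self.mito] = self.mito_share * mean_mito
        return out / out.sum()


def _nb_counts(
    rng: np.random.Generator, lam: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draws with mean lam and NB dispersion (var = mu + disp*mu^2)."""
    if dispersion <= 0:
        return rng.poisson(lam)
    g = rng.gamma(1.0 / dispersion, dispersion, size=lam.shape)
    return rng.poisson(lam * g)


def _arm_stage_props(config: GeneratorConfig, arm: str) -> np.ndarray:
    props = np.array([config.stage_proportions[s] for s in STAGES], dtype=float)
    early = [STAGES.index(s) for s in EARLY_STAGES]
    props[early] *= config.epcam_enrichment_factor
    props /= props.sum()
    eff = config.effects.get(arm)
    if eff is not None and eff.stage_shift:
        for stage, delta in eff.stage_shift.items():
            props[STAGES.index(stage)] += delta
        props = np.clip(props, 1e-9, None)
        props /= props.sum()
    return props


def simulate_experiment(
    config: GeneratorConfig,
) -> tuple[DualSpeciesCounts, GroundTruth]:
    """Generate dual-species UMI count matrices with ground-truth annotations.

    Deterministic under ``config.seed``: identical configs produce
    bit-identical matrices and truth tables.
    """
    config.validate()
    universe = build_gene_universe(config)
    rng = np.random.default_rng(config.seed)

    rat_roster = universe.table[universe.table["species"] == "rat"].reset_index(
        drop=True
    )
    mouse_roster = universe.table[
        universe.table["species"] == "mouse"
    ].reset_index(drop=True)
    models = {
        "rat": _SpeciesModel(rat_roster, config, rng, apply_effects=True),
        "mouse": _SpeciesModel(mouse_roster, config, rng, apply_effects=False),
    }

    base_props = np.array(
        [config.stage_proportions[s] for s in STAGES], dtype=float
    )
    base_props /= base_props.sum()
    a, b = config.mito_beta
    mean_mito = a / (a + b)
    ambient = {
        sp_name: model.ambient_profile(base_props, mean_mito)
        for sp_name, model in models.items()
    }

    r = config.ambient_cross_species_rate
    disp = config.dispersion
    mu_ls = np.log(config.mean_umis_per_cell) - 0.5 * config.libsize_sigma**2

    rat_blocks: list[sp.csr_matrix] = []
    mouse_blocks: list[sp.csr_matrix] = []
    barcodes: list[str] = []
    truth_rows: list[pd.DataFrame] = []

    for arm in config.treatments:
        eff = config.effects.get(arm, ArmEffects())
        apop_frac = (
            eff.apoptotic_fraction
            if eff.apoptotic_fraction is not None
            else config.apoptotic_fraction
        )
        arm_props = _arm_stage_props(config, arm)
        for rep in range(config.replicates_per_arm):
            n = config.cells_per_replicate
            props = arm_props * rng.lognormal(
                0.0, config.proportion_noise_sigma, size=len(STAGES)
            )
            props /= props.sum()
            stages = rng.choice(len(STAGES), size=n, p=props)
            is_rat = rng.random(n) < eff.species_fraction_rat
            libsize = rng.lognormal(mu_ls, config.libsize_sigma, size=n)
            mito_frac = rng.beta(a, b, size=n)
            apoptotic = rng.random(n) < apop_frac

            counts = {
                "rat": np.zeros((n, len(models["rat"].genes)), dtype=np.int64),
                "mouse": np.zeros((n, len(models["mouse"].genes)), dtype=np.int64),
            }
            for own, other in (("rat", "mouse"), ("mouse", "rat")):
                own_mask = is_rat if own == "rat" else ~is_rat
                if not own_mask.any():
                    continue
                model = models[own]
                shares = model.shares[arm]
                for si in range(len(STAGES)):
                    for ap in (0, 1):
                        idx = np.flatnonzero(
                            own_mask & (stages == si) & (apoptotic == bool(ap))
                        )
                        if idx.size == 0:
                            continue
                        own_budget = (1.0 - r) * libsize[idx]
                        lam_nuc = (
                            (own_budget * (1.0 - mito_frac[idx]))[:, None]
                            * shares[si, ap][None, :]
                        )
                        counts[own][np.ix_(idx, model.nuclear)] = _nb_counts(
                            rng, lam_nuc, disp
                        )
                        lam_mito = (
                            (own_budget * mito_frac[idx])[:, None]
                            * model.mito_share[None, :]
                        )
                        counts[own][np.ix_(idx, model.mito)] = _nb_counts(
                            rng, lam_mito, disp
                        )
                # ambient soup of the *other* species, Poisson (pooled source)
                if r > 0:
                    idx = np.flatnonzero(own_mask)
                    lam_amb = (r * libsize[idx])[:, None] * ambient[other][None, :]
                    counts[other][idx] = rng.poisson(lam_amb)

            rat_blocks.append(sp.csr_matrix(counts["rat"], dtype=np.int32))
            mouse_blocks.append(sp.csr_matrix(counts["mouse"], dtype=np.int32))
            rep_name = f"{arm}_r{rep + 1}"
            bcs = [f"{rep_name}_c{i + 1:05d}" for i in range(n)]
            barcodes.extend(bcs)
            truth_rows.append(
                pd.DataFrame(
                    {
                        "species": np.where(is_rat, "rat", "mouse"),
                        "stage": [STAGES[s] for s in stages],
                        "apoptotic": apoptotic,
                        "treatment": arm,
                        "replicate": rep_name,
                        "mito_fraction": mito_frac,
                        "library_size": libsize,
                    },
                    index=pd.Index(bcs, name="barcode"),
                )
            )

    fc_rows = []
    for arm in config.treatments:
        eff = config.effects.get(arm)
        if eff is None:
            continue
        for stage, folds in eff.expression_folds.items():
            for gene, fold in folds.items():
                fc_rows.append(
                    {
                        "treatment": arm,
                        "stage": stage,
                        "gene": gene,
                        "fold": fold,
                        "log2fc": float(np.log2(fold)),
                    }
                )
    fold_changes = pd.DataFrame(
        fc_rows, columns=["treatment", "stage", "gene", "fold", "log2fc"]
    )

    counts_out = DualSpeciesCounts(
        rat=sp.vstack(rat_blocks, format="csr"),
        mouse=sp.vstack(mouse_blocks, format="csr"),
        rat_genes=models["rat"].genes,
        mouse_genes=models["mouse"].genes,
        barcodes=pd.Index(barcodes, name="barcode"),
    )
    truth = GroundTruth(
        cells=pd.concat(truth_rows), fold_changes=fold_changes
    )
    logger.info(
        "simulated %d cells x (%d rat + %d mouse) genes",
        counts_out.n_cells,
        len(counts_out.rat_genes),
        len(counts_out.mouse_genes),
    )
    return counts_out, truth


def apply_epcam_enrichment(
    truth_cells: pd.DataFrame,
    enrichment_factor: float,
    seed: int | None = None,
) -> pd.Index:
    """Resample a cell population enriched for premeiotic stages.

    Models EpCAM magnetic selection: the sampling weight of the three early
    stages is multiplied by ``enrichment_factor`` and the population is
    resampled (with replacement) to the same total cell count. A factor of 1,
    or a population containing no early-stage cells, returns the input
    barcodes unchanged.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    early = truth_cells["stage"].isin(EARLY_STAGES).to_numpy()
    if enrichment_factor == 1 or not early.any():
        return truth_cells.index
    w = np.where(early, enrichment_factor, 1.0)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(truth_cells), size=len(truth_cells), replace=True, p=w)
    return truth_cells.index[pick]


# ---------------------------------------------------------------------------
# named experiment presets
# ---------------------------------------------------------------------------

PRESET_NAMES = (
    "thawed_epcam",
    "transplanted_unselected",
    "pure_species",
    "null",
)


def preset(name: str, seed: int = 0, **overrides) -> GeneratorConfig:
    """Named study-condition presets.

    ``thawed_epcam``
        EpCAM-enriched fresh / short-frozen / long-frozen arms analyzed
        post-thaw; freezing induces the cell-stress program in SSCs, graded
        short < long.
    ``transplanted_unselected``
        Unselected cells recovered from transplanted testes; the long-frozen
        arm has more SSCs and differentiating spermatogonia, fewer elongating
        spermatids, and suppressed Prm1/Tnp1/Tnp2 in round spermatids.
    ``pure_species``
        One pure-rat and one pure-mouse sample of 10,000 cells each, used to
        validate the species classifier.
    ``null``
        Three arms with no planted effects (type-I error studies).
    """
    if name == "thawed_epcam":
        stress_up = lambda f: {"SSC": {g: f for g in STRESS_GENES}}
        cfg = GeneratorConfig(
            treatments=("fresh", "short_frozen", "long_frozen"),
            epcam_enrichment_factor=5.0,
            effects={
                "short_frozen": ArmEffects(expression_folds=stress_up(1.5)),
                "long_frozen": ArmEffects(expression_folds=stress_up(2.25)),
            },
            seed=seed,
        )
    elif name == "transplanted_unselected":
        round_folds = {
            "round spermatid": {
                "Prm1": 1 / 2.0,
                "Tnp1": 1 / 2.1,
                "Tnp2": 1 / 1.5,
            }
        }
        sf_folds = {
            "round spermatid": {
                "Prm1": 2.3 / 2.0,
                "Tnp1": 1.7 / 2.1,
                "Tnp2": 1.4 / 1.5,
            }
        }
        cfg = GeneratorConfig(
            treatments=(
                "transplanted_fresh",
                "transplanted_short_frozen",
                "transplanted_long_frozen",
            ),
            effects={
                "transplanted_short_frozen": ArmEffects(
                    expression_folds=sf_folds
                ),
                "transplanted_long_frozen": ArmEffects(
                    expression_folds=round_folds,
                    stage_shift={
                        "SSC": 0.10,
                        "differentiating spermatogonia": 0.04,
                        "elongating spermatid": -0.14,
                    },
                ),
            },
            seed=seed,
        )
    elif name == "pure_species":
        cfg = GeneratorConfig(
            treatments=("pure_rat", "pure_mouse"),
            replicates_per_arm=1,
            cells_per_replicate=10_000,
            effects={
                "pure_rat": ArmEffects(species_fraction_rat=1.0),
                "pure_mouse": ArmEffects(species_fraction_rat=0.0),
            },
            seed=seed,
        )
    elif name == "null":
        cfg = GeneratorConfig(
            treatments=("fresh", "short_frozen", "long_frozen"), seed=seed
        )
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise TypeError(f"unknown GeneratorConfig field {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg
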