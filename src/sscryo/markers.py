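"""Canonical gene panels and programs for rat germ-cell analysis.

The seven germ-cell states are ordered along the spermatogenic lineage, from
self-renewing spermatogonial stem cells (SSCs) through mitotic amplification,
meiosis, and spermiogenesis. Marker panels follow the standard rodent
spermatogenesis atlas genes: *Etv5*/*Ret* for SSCs, *Sall4*/*Uchl1*/*Crabp1*
for progenitors, *Kit* for differentiating spermatogonia, *Stra8*/*Mei1*
(preleptotene) and *Sycp3*/*Tex101* (leptotene/zygotene) for early
spermatocytes, *Piwil1* for pachytene (late) spermatocytes, *Acrv1*/*Catsper3*
for round spermatids, and the transition proteins and protamines
(*Tnp1*/*Tnp2*/*Prm1*/*Prm2*) for elongating spermatids.
"""

from __future__ import annotations

STAGES: tuple[str, ...] = (
    "SSC",
    "progenitor",
    "differentiating spermatogonia",
    "early spermatocyte",
    "late spermatocyte",
    "round spermatid",
    "elongating spermatid",
)

#: Stages enriched by EpCAM magnetic selection (premeiotic compartment).
EARLY_STAGES: tuple[str, ...] = STAGES[:3]

#: Default marker panels, one per germ-cell state, in canonical stage order.
MARKER_PANELS: dict[str, tuple[str, ...]] = {
    "SSC": ("Etv5", "Ret"),
    "progenitor": ("Sall4", "Uchl1", "Crabp1"),
    "differentiating spermatogonia": ("Kit",),
    "early spermatocyte": ("Stra8", "Mei1", "Sycp3", "Tex101"),
    "late spermatocyte": ("Piwil1",),
    "round spermatid": ("Acrv1", "Catsper3"),
    "elongating spermatid": ("Tnp1", "Tnp2", "Prm1", "Prm2"),
}

#: 38-gene proapoptotic program used for per-cell apoptosis module scoring.
PROAPOPTOTIC_GENES: tuple[str, ...] = (
    "Acin1", "Apaf1", "Bad", "Bak1", "Bax", "Bcl2l11", "Bcl2l14", "Bid",
    "Bik", "Bmf", "Bnip3l", "Bok", "Casp2", "Casp3", "Casp6", "Casp7",
    "Casp8", "Casp9", "Casp12", "Dapk1", "Dapk2", "Dapk3", "Dedd", "Dffa",
    "Diablo", "Ercc2", "Ercc3", "Fas", "Faslg", "Foxo3", "Tnf", "Tnfrsf10b",
    "Tnfrsf1a", "Tnfrsf1b", "Tnfsf14", "Tp53", "Tradd", "Traf3",
)

#: Cell-stress / immediate-early program used to plant the freezing response.
STRESS_GENES: tuple[str, ...] = (
    "Hspa1a", "Hspa1b", "Hspa8", "Hsp90aa1", "Hspb1", "Hspe1", "Hsph1",
    "Dnajb1", "Fos", "Fosb", "Jun", "Junb", "Atf3", "Egr1", "Ier2", "Ier3",
    "Dusp1", "Zfp36", "Btg2", "Socs3",
)

#: Mitochondrially encoded genes (the 13 protein-coding mt transcripts).
MITO_GENES: tuple[str, ...] = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)


def all_panel_genes(panels: dict[str, tuple[str, ...]] | None = None) -> list[str]:
    """Flat, order-preserving list of every marker gene across panels."""
    panels = MARKER_PANELS if panels is None else panels
    out: list[str] = []
    for genes in panels.values():
        for g in genes:
            if g not in out:
                out.append(g)
    return out
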