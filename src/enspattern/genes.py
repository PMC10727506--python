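"""Bundled gene annotations.

Murine mitochondrial annotation (the 37 genes encoded on the mouse
mitochondrial genome: 13 protein-coding, 2 rRNA, 22 tRNA), default lineage
marker signatures for cluster annotation, and a cell-cycle gene list.
"""

from __future__ import annotations

# The 37 genes of the mouse mitochondrial genome (MGI symbols).
MOUSE_MITO_GENES: tuple[str, ...] = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
    "mt-Rnr1", "mt-Rnr2",
    "mt-Tf", "mt-Tv", "mt-Tl1", "mt-Ti", "mt-Tq", "mt-Tm", "mt-Tw", "mt-Ta",
    "mt-Tn", "mt-Tc", "mt-Ty", "mt-Ts1", "mt-Td", "mt-Tk", "mt-Tg", "mt-Tr",
    "mt-Th", "mt-Ts2", "mt-Tl2", "mt-Te", "mt-Tt", "mt-Tp",
)

#: Marker signatures used to annotate graph clusters by lineage:
#: neural-crest-derived enteric neurons (NENs) express Ret; enteric neuroglia
#: express Sox10/Ncam1; mesoderm-derived enteric neurons (MENs) co-express
#: Calcb (CGRP), Met, and Cdh3.
DEFAULT_SIGNATURES: dict[str, frozenset[str]] = {
    "NEN": frozenset({"Ret"}),
    "neuroglia": frozenset({"Sox10", "Ncam1"}),
    "MEN": frozenset({"Calcb", "Met", "Cdh3"}),
}

# Canonical murine cell-cycle genes (S and G2/M regulators, replication
# machinery, mitotic kinases and spindle components).
_CORE_CC_GENES: tuple[str, ...] = (
    "Mcm2", "Mcm3", "Mcm4", "Mcm5", "Mcm6", "Mcm7", "Pcna", "Top2a", "Ect2",
    "Ccnb1", "Ccnb2", "Ccna2", "Ccne1", "Ccne2", "Cdk1", "Cdc20", "Cdc45",
    "Cdc6", "Cdt1", "Aurka", "Aurkb", "Plk1", "Bub1", "Bub1b", "Birc5",
    "Mki67", "Foxm1", "Tyms", "Rrm1", "Rrm2", "Fen1", "Gins2", "Hells",
    "Ung", "Pola1", "Prim1", "Gmnn", "Slbp", "E2f1", "Esco2", "Cenpa",
    "Cenpe", "Cenpf", "Kif11", "Kif23", "Kif2c", "Ndc80", "Nuf2", "Nusap1",
    "Tpx2", "Ube2c", "Anln", "Cks1b", "Cks2", "Dtl", "Uhrf1", "Chaf1b",
    "Exo1", "Msh2", "Rad51", "Rad51ap1", "Blm", "Brip1", "Casp8ap2",
    "Ckap2", "Ckap5", "Dlgap5", "Gtse1", "Hjurp", "Hmgb2", "Lbr", "Psrc1",
    "Smc4", "Tacc3", "Ttk", "Tubb4b", "Usp1", "Wdr76", "Clspn", "Pold3",
    "Cdca2", "Cdca3", "Cdca8", "Mad2l1", "Ncapd2",
)


def default_cc_genes(n: int = 500) -> list[str]:
    """Return the bundled cell-cycle gene list, size-matched to ``n``.

    This is a synthetic stand-in reference list: it starts with canonical
    murine cell-cycle symbols and is padded with systematic ``CcgNNN``
    symbols to reach ``n`` entries. It is the gene set the synthetic
    cell-cycle cohort plants its angular signal on; analyses of real data
    should supply a curated cell-cycle annotation instead.
    """
    if n <= len(_CORE_CC_GENES):
        return list(_CORE_CC_GENES[:n])
    pad = [f"Ccg{i:03d}" for i in range(len(_CORE_CC_GENES), n)]
    return list(_CORE_CC_GENES) + pad
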