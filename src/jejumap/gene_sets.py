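"""Marker panels and curated gene sets used throughout the pipeline.

Two-tier cell annotation panels (major lineages, then T/ILC/NK subtypes),
the inflammation gene list, T-cell state panels, cell-cycle phase sets and
the ligand–receptor pair table. Symbols follow the pig-atlas convention of
human-orthologue gene names (hence e.g. HLA-DRA).
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Annotation marker panels
# ---------------------------------------------------------------------------

#: Major lineage panel. Order matters: annotation ties break by panel order.
LINEAGE_MARKERS: dict[str, list[str]] = {
    "epithelial": ["EPCAM", "KRT8"],
    "plasma": ["JCHAIN", "MZB1"],
    "B": ["CD19", "CD79A", "CD79B", "BACH2"],
    "T/ILC/NK": ["CD3E", "ZAP70", "CD4", "IL7R", "CD8A", "GNLY", "NKG7", "PRF1"],
    "myeloid": ["CD68", "CSF2RB", "C1QC", "APOE", "FCER1A", "KIT"],
    "mesenchymal": ["CALD1", "VIM", "ZEB2"],
}

#: T/ILC/NK subtype panel, applied only within the T/ILC/NK compartment.
T_SUBTYPE_MARKERS: dict[str, list[str]] = {
    "ILC": ["KLRB1", "CSF2"],
    "NK": ["PRF1", "NKG7", "EOMES"],
    "CD4 ab T": ["CD4"],
    "CD8 ab T": ["CD8B"],
    "gd T": ["BLK"],
}

#: Plasma-cell subtype panel. SYNTHETIC fixture: the study names no formal
#: panel, so subtypes are marked with the genes it reports as distinguishing
#: the three plasma populations (Type 3: stable high IGHM plus PRDX4/ATP5PO;
#: Type 1/2: early-plasma vs B-receptor-component genes).
PLASMA_SUBTYPE_MARKERS: dict[str, list[str]] = {
    "Plasma Type1": ["CD38", "CD27"],
    "Plasma Type2": ["CD79A", "CD79B"],
    "Plasma Type3": ["IGHM", "PRDX4", "ATP5PO"],
}

# ---------------------------------------------------------------------------
# Score gene sets
# ---------------------------------------------------------------------------

#: Inflammation-related genes (literature-compiled list, kept verbatim —
#: "PRF" resolves to PRF1 through GENE_ALIASES).
INFLAMMATION_GENES: list[str] = [
    "GZMB", "GZMA", "PRF", "IFNG", "IFNGR1", "ISG20", "IL4", "IL4R", "IL5",
    "IL6", "IL10", "IRF2", "IL12B", "IL17A", "IL17F", "IL17RA", "IL2",
    "IL2RB", "IL21", "IL21R", "NFKBIA", "RORA", "RORC", "S100A8", "S100A9",
    "STAT1", "STAT3", "STAT4", "TGFB1I1", "TNFRSF1B", "TNF",
]

#: T-cell functional state panels.
T_STATE_PANELS: dict[str, list[str]] = {
    "memory": ["KLRB1", "IL7R"],
    "tissue_resident": ["RUNX3", "CD69", "NR4A1", "CXCR6", "CD103"],
    "cytotoxic": ["GZMA", "GZMB", "PRF1", "GNLY", "CST7", "TNFSF10"],
    "exhaustion": ["PDCD1", "CTLA4", "HAVCR2", "LAG3"],
    "co_stimulatory": ["CD28", "CD226", "ICOS", "TNFRSF9"],
}

#: Cell-cycle phase sets (canonical S / G2M signature genes).
S_PHASE_GENES: list[str] = [
    "MCM5", "PCNA", "TYMS", "FEN1", "MCM2", "MCM4", "RRM1", "UNG", "GINS2",
    "MCM6", "CDCA7", "DTL", "PRIM1", "UHRF1", "HELLS",
]
G2M_PHASE_GENES: list[str] = [
    "HMGB2", "CDK1", "NUSAP1", "UBE2C", "BIRC5", "TPX2", "TOP2A", "NDC80",
    "CKS2", "NUF2", "CKS1B", "MKI67", "TMPO", "CENPF",
]

#: Symbol aliases mapping printed variants onto the gene universe.
GENE_ALIASES: dict[str, str] = {
    "PRF": "PRF1",
    "CD103": "ITGAE",
}

# ---------------------------------------------------------------------------
# Ligand–receptor pairs
# ---------------------------------------------------------------------------

#: (ligand, receptor) rows; complexes are "_"-joined subunit lists.
LR_PAIRS: list[tuple[str, str]] = [
    ("B2M", "KLRD1"),
    ("CD22", "PTPRC"),
    ("HSPA8", "LDLR"),
    ("CCL5", "CCR4"),
    ("CCL5", "CCR5"),
    ("CCL5", "CXCR3"),
    ("CCL5", "SDC1"),
    ("CCL5", "CCRL2"),
    ("CCL5", "DPP4"),
    ("CALM1", "KCNQ5"),
    ("CALM1", "PDE1C"),
    ("CALM1", "TRPC3"),
    ("CALM1", "GLP1R"),
    ("CALM1", "HMMR"),
    ("ADAM10", "TSPAN5"),
    ("CD48", "CD2"),
    ("LCK", "CD8A_CD8B"),
    ("LGALS1", "PTPRC"),
    ("MAML2", "NOTCH1"),
    ("MAML2", "NOTCH2"),
    ("TGFB1", "TGFBR1_TGFBR2"),
    ("TGFB1", "CXCR4"),
    ("HLA-DRA", "CD4"),
    ("TFF3", "CXCR4"),
    ("CD40LG", "CD53"),
]


def resolve_symbol(symbol: str, universe: set[str] | None = None) -> str:
    """Map a printed symbol onto the working gene universe via the alias map.

    If ``universe`` is given, the alias is applied only when the verbatim
    symbol is absent but the alias target is present.
    """
    if universe is None:
        return GENE_ALIASES.get(symbol, symbol)
    if symbol in universe:
        return symbol
    alias = GENE_ALIASES.get(symbol)
    if alias is not None and alias in universe:
        return alias
    return symbol


def all_named_genes() -> list[str]:
    """Every named symbol referenced by any panel, set or LR pair (deduplicated)."""
    seen: dict[str, None] = {}
    for panel in (LINEAGE_MARKERS, T_SUBTYPE_MARKERS, PLASMA_SUBTYPE_MARKERS,
                  T_STATE_PANELS):
        for genes in panel.values():
            for g in genes:
                seen.setdefault(resolve_symbol(g), None)
    for g in INFLAMMATION_GENES + S_PHASE_GENES + G2M_PHASE_GENES:
        seen.setdefault(resolve_symbol(g), None)
    for lig, rec in LR_PAIRS:
        for entity in (lig, rec):
            for sub in entity.split("_"):
                seen.setdefault(resolve_symbol(sub), None)
    return list(seen)
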