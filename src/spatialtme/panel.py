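"""Built-in gene panel, cell-type signature matrix, and pathway gene sets.

The signature is a small synthetic stand-in for a published tumor-microenvironment
profile matrix (immune + stromal cell types): 110 panel genes x 12 cell types,
with canonical lineage markers given high mean expression in their own column
and a low deterministic baseline elsewhere.  It exists so that the whole
pipeline is testable without downloading any reference data; a real signature
(e.g. safeTME) can be loaded from CSV with
:func:`spatialtme.deconvolution.read_signature_csv`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CELL_TYPES = [
    "CD8_T",
    "CD4_T",
    "Treg",
    "NK",
    "B",
    "monocyte",
    "macrophage",
    "neutrophil",
    "mDC",
    "pDC",
    "fibroblast",
    "endothelial",
]

#: canonical lineage markers per cell type (5 each)
MARKERS: dict[str, list[str]] = {
    "CD8_T": ["CD8A", "CD8B", "GZMK", "GZMA", "PRF1"],
    "CD4_T": ["CD4", "IL7R", "CD40LG", "CCR7", "TRAC"],
    "Treg": ["FOXP3", "IL2RA", "CTLA4", "IKZF2", "TNFRSF4"],
    "NK": ["NCAM1", "NKG7", "KLRD1", "GNLY", "NCR1"],
    "B": ["MS4A1", "CD19", "CD79A", "CD79B", "IGHM"],
    "monocyte": ["CD14", "FCN1", "S100A8", "S100A9", "VCAN"],
    "macrophage": ["CD68", "CD163", "MRC1", "MSR1", "MARCO"],
    "neutrophil": ["FCGR3B", "CSF3R", "CXCR2", "S100A12", "ELANE"],
    "mDC": ["CD1C", "FCER1A", "CLEC9A", "BATF3", "ITGAX"],
    "pDC": ["CLEC4C", "IL3RA", "LILRA4", "IRF7", "TCF4"],
    "fibroblast": ["COL1A1", "COL1A2", "ACTA2", "PDGFRB", "FAP"],
    "endothelial": ["PECAM1", "CDH5", "VWF", "CLDN5", "KDR"],
}

#: epithelial / tumor-intrinsic and pathway genes completing the 100-gene panel
TUMOR_GENES = [
    "EPCAM", "KRT8", "KRT18", "KRT19", "PAX8", "WT1", "MUC16",
    "TFPI2", "PIGR", "EYA2", "ID1", "H2BC10", "ITLN1", "CYBB",
]

OTHER_GENES = [
    "ACTB", "GAPDH", "B2M", "PPIA", "UBC", "TBP",
    "LDHA", "PGK1", "HIF1A", "SDHA",
    "MYC", "CCND1", "VEGFA", "MKI67",
    "NFKB1", "RELA", "TGFB1", "SMAD3",
    "JAK2", "STAT3", "PIK3CA", "MTOR",
    "CTNNB1", "WNT7A", "KRAS", "MAPK1",
    "ATG5", "ATG7", "MAP1LC3B", "SQSTM1", "BECN1",
    "TP53", "CD274", "PDCD1", "GZMB", "IFNG",
]

PANEL_GENES = (
    [g for markers in MARKERS.values() for g in markers] + TUMOR_GENES + OTHER_GENES
)

_MARKER_LEVEL = 30.0
_BASELINE_SCALE = 0.5
_SIGNATURE_SEED = 20240517  # fixed: the signature is a constant object


def builtin_signature() -> pd.DataFrame:
    """Return the built-in 110-gene x 12-cell-type signature matrix.

    Rows are genes, columns cell types; entries are relative mean expression.
    Deterministic (internal fixed seed): repeated calls return identical
    matrices.
    """
    rng = np.random.default_rng(_SIGNATURE_SEED)
    n_genes, n_types = len(PANEL_GENES), len(CELL_TYPES)
    base = _BASELINE_SCALE * rng.lognormal(mean=-1.0, sigma=0.8, size=(n_genes, n_types))
    sig = pd.DataFrame(base, index=PANEL_GENES, columns=CELL_TYPES)
    for ct, markers in MARKERS.items():
        for g in markers:
            sig.loc[g, ct] = _MARKER_LEVEL
    # lymphoid lineages share TRAC / low-level cytotoxic genes
    sig.loc["TRAC", ["CD8_T", "Treg"]] = 10.0
    sig.loc["NKG7", "CD8_T"] = 8.0
    sig.loc["GZMB", ["CD8_T", "NK"]] = 6.0
    sig.loc["IFNG", ["CD8_T", "NK"]] = 3.0
    return sig


def tumor_profile() -> pd.Series:
    """Mean expression profile of carcinoma cells over the panel.

    Used by the synthetic generator for the tumor fraction of PanCK
    segments; deliberately not a signature column (the deconvolution
    signature covers immune/stromal types only, mirroring tumor-agnostic
    profile matrices).
    """
    rng = np.random.default_rng(_SIGNATURE_SEED + 1)
    prof = pd.Series(
        0.3 * rng.lognormal(mean=-1.0, sigma=0.6, size=len(PANEL_GENES)),
        index=PANEL_GENES,
    )
    for g in TUMOR_GENES:
        prof[g] = 20.0
    for g in ["ACTB", "GAPDH", "B2M", "PPIA", "LDHA", "PGK1", "MKI67", "CCND1", "MYC"]:
        prof[g] = 8.0
    return prof


#: synthetic stand-in pathway gene sets over the panel (hallmark/WikiPathways-like)
PATHWAY_SETS: dict[str, list[str]] = {
    "NFKB_SIGNALING": ["NFKB1", "RELA", "CYBB", "CD274", "TNFRSF4", "IFNG"],
    "TGFB_SIGNALING": ["TGFB1", "SMAD3", "ACTA2", "PDGFRB", "COL1A1", "ID1"],
    "JAK_STAT_SIGNALING": ["JAK2", "STAT3", "IL7R", "IL3RA", "IL2RA", "CSF3R"],
    "PI3K_MTOR_SIGNALING": ["PIK3CA", "MTOR", "VEGFA", "CCND1", "HIF1A", "KDR"],
    "WNT_SIGNALING": ["CTNNB1", "WNT7A", "MYC", "CCND1", "PAX8", "TCF4"],
    "RAS_SIGNALING": ["KRAS", "MAPK1", "MYC", "VEGFA", "ELANE", "MKI67"],
    "WARBURG_EFFECT": ["LDHA", "PGK1", "HIF1A", "GAPDH", "SDHA", "MYC"],
    "AUTOPHAGY": ["ATG5", "ATG7", "MAP1LC3B", "SQSTM1", "BECN1", "MTOR"],
}

#: which of the pathway sets are read as immune rather than cancer pathways
IMMUNE_PATHWAYS = ["NFKB_SIGNALING", "TGFB_SIGNALING", "JAK_STAT_SIGNALING"]
CANCER_PATHWAYS = [p for p in PATHWAY_SETS if p not in IMMUNE_PATHWAYS]


def builtin_pathways() -> dict[str, list[str]]:
    """Return the built-in pathway gene sets (name -> gene list)."""
    return {k: list(v) for k, v in PATHWAY_SETS.items()}
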