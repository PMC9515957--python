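"""Shared defaults: tissues, thresholds, gene sets, marker tables.

Every threshold that carries scientific meaning (expansion cutoff, clone-size
class bounds, public-clone bounds, marker-finding thresholds, spatial profile
range) lives here under one name so that the CLI, the library and the docs
agree on a single source of defaults.
"""

from __future__ import annotations

import importlib.resources

import yaml

TISSUES = ("TUMOR", "NAT", "PBMC")

#: 7-way tissue-distribution pattern labels, in canonical order.
PATTERNS = ("TUMOR", "NAT", "PBMC", "TN", "TP", "PN", "ALL")

#: Clonal-expansion cutoff for bulk repertoires (strict: frequency > 1%).
EXPANDED_THRESHOLD = 0.01

#: Clone-size class boundaries for single-cell clonotypes:
#: singleton = 1 cell, small = 2-4, medium = 5-20, large = >20.
SIZE_CLASS_BOUNDS = (2, 5, 21)
SIZE_CLASSES = ("singleton", "small", "medium", "large")

#: Public-clonotype calling: detected in > 10 cells in at least one tumor
#: (i.e. >= 11) and shared by >= 10 patients.
PUBLIC_MIN_PATIENTS = 10
PUBLIC_MIN_CELLS = 11

#: Marker-finding thresholds (fraction of cells expressing; natural-log FC).
MIN_PCT = 0.25
MIN_LOGFC = 0.25

#: Spatial density profile extent (signed µm around the tumor border).
PROFILE_RANGE_UM = 500.0
PROFILE_BIN_UM = 50.0

#: Protein-name aliases mapped to HGNC symbols used in expression matrices.
GENE_ALIASES = {
    "TIM3": "HAVCR2",
    "PD1": "PDCD1",
    "CD25": "IL2RA",
    "TNFSR9": "TNFRSF9",
    "TNFSF9": "TNFRSF9",
}

#: Functional gene sets scored per cell (exhaustion / activation / effector).
GENE_SETS = {
    "exhaustion": ["ICOS", "HAVCR2", "CTLA4", "PDCD1", "LAG3", "TIGIT"],
    "activation": ["TNFRSF9", "CD69", "IL2RA"],
    "effector": ["GZMB", "PRF1", "IFNG"],
    "proliferation": ["MKI67"],
}


def resolve_gene(name: str) -> str:
    """Map a protein alias (e.g. ``PD1``) to its HGNC symbol (``PDCD1``)."""
    name = name.strip().upper()
    return GENE_ALIASES.get(name, name)


def load_marker_table(path=None) -> dict[str, list[str]]:
    """Load the phenotype -> marker-gene table.

    Parameters
    ----------
    path
        Optional YAML file with the same structure as the packaged default
        (``data/marker_genes.yaml``). When omitted the packaged table is used.
    """
    if path is None:
        ref = importlib.resources.files("tilseq").joinpath("data/marker_genes.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table = yaml.safe_load(text)
    out = {}
    for phenotype, genes in table.items():
        if not genes:
            raise ValueError(f"marker table: empty gene list for {phenotype!r}")
        out[str(phenotype)] = [resolve_gene(g) for g in genes]
    return out
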