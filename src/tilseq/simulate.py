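"""Synthetic multi-tissue TCR / single-cell / spatial data with ground truth.

The generator emulates the statistical structure of a nephrectomy-cohort
T-cell study: per patient, a heavy-tailed (Zipf) clone-abundance law with a
dominant clone in the few-to-tens-of-percent range; a 7-way tissue-occupancy
pattern per clone over tumor / NAT / PBMC; deep multinomial read sampling per
tissue; convergent nucleotypes (several nucleotide sequences per CDR3
protein); planted interior-motif families for specificity grouping; per-cell
paired TRA/TRB chains with configurable doublet and chain-capture rates;
phenotype-dependent marker-gene expression with CD4/CD8/double-positive
lineage encoding; a donor-wise control TRB library with a planted
patient-unique fraction; and inhomogeneous-Poisson spatial cell tables around
a tumor border. Everything derives from one integer seed, and the planted
parameters are returned as ground truth for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from shapely.geometry import LineString, Polygon

from .config import GENE_SETS, PATTERNS, TISSUES, load_marker_table
from .repertoire import Repertoire
from .spatial import BorderGeometry

AA = "ACDEFGHIKLMNPQRSTVWY"
# interior amino-acid frequencies, loosely beta-chain-like (glycine/serine rich)
AA_FREQS = np.array([
    0.06, 0.01, 0.05, 0.06, 0.03, 0.12, 0.02, 0.03, 0.02, 0.07,
    0.02, 0.04, 0.04, 0.05, 0.05, 0.11, 0.07, 0.05, 0.02, 0.08,
])
AA_FREQS = AA_FREQS / AA_FREQS.sum()

CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}

V_PREFIXES = ("CASS", "CASR", "CSAR", "CAWS")
J_SUFFIXES = ("YGYTF", "EQFF", "ETQYF", "GELFF", "NQPQH")
TRA_PREFIXES = ("CAV", "CAG", "CIV")
TRA_SUFFIXES = ("DKLIF", "NARLM", "GGSYIPTF")

PATTERN_TISSUES = {
    "TUMOR": ("TUMOR",), "NAT": ("NAT",), "PBMC": ("PBMC",),
    "TN": ("TUMOR", "NAT"), "TP": ("TUMOR", "PBMC"), "PN": ("NAT", "PBMC"),
    "ALL": ("TUMOR", "NAT", "PBMC"),
}

CD8_PHENOTYPES = ("T_eff", "T_em", "T_cm", "T_scm", "naive")
CD4_PHENOTYPES = ("Th1", "Th2", "Th17", "T_reg", "naive", "T_cm", "T_scm")


@dataclass
class SynthConfig:
    """Planted parameters of the synthetic study. Defaults are the study
    conditions (dominant-clone range, depths, rates); see docs/methods.md."""

    seed: int = 0
    n_patients: int = 3
    clones_per_patient: int = 500
    zipf_exponent: float = 1.1
    # TUMOR, NAT, PBMC, TN, TP, PN, ALL
    tissue_pattern_probs: tuple = (0.25, 0.10, 0.15, 0.10, 0.10, 0.05, 0.25)
    depths: dict = field(default_factory=lambda: dict.fromkeys(TISSUES, 100_000))
    nonproductive_rate: float = 0.02
    convergence_rate: float = 0.10
    # motif families planted into tumor-clone interiors
    motif_families: tuple = ("QGAD", "WNTG", "RDSY")
    motif_family_sizes: tuple = (5, 4, 3)
    # single cell
    sc_cells_per_tissue: int = 1500
    doublet_rate: float = 0.03
    both_chain_rate: float = 0.546
    # conditional on a CD8 clone; with cd8_clone_fraction 0.6 and equal cells
    # per tissue this yields ~2.2% DP overall with ~83% of DP cells in tumor
    dp_rate_by_tissue: dict = field(default_factory=lambda: {
        "TUMOR": 0.0913, "NAT": 0.0094, "PBMC": 0.0094})
    cd8_clone_fraction: float = 0.6
    marker_shift_fold: float = 2.0
    exhaustion_shift: float = 1.0  # ln-units added to exhaustion genes of TUMOR-pattern cells
    base_log_mean: float = 2.0
    expr_noise_sd: float = 0.2
    n_genes: int = 300
    # control library screen
    control_n_donors: int = 55
    patient_unique_rate: float = 0.639
    # spatial
    spatial_domain_um: tuple = (2000.0, 1000.0)
    border_shape: str = "straight"  # or "sine"
    spatial_intensities: dict = field(default_factory=lambda: {
        "CD8": (500.0, 100.0), "CD4": (300.0, 150.0)})  # (inside, outside) per mm^2
    caix_intensity: float = 800.0
    ki67_prob: float = 0.15

    def validate(self) -> None:
        problems = []
        if abs(sum(self.tissue_pattern_probs) - 1.0) > 1e-9 or len(self.tissue_pattern_probs) != 7:
            problems.append("tissue_pattern_probs must be a 7-vector summing to 1")
        for name in ("nonproductive_rate", "convergence_rate", "doublet_rate",
                     "both_chain_rate", "patient_unique_rate", "ki67_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0,1], got {v}")
        for tissue, depth in self.depths.items():
            if depth < 100:
                problems.append(f"depth for {tissue} must be >= 100")
        for cls, (lin, lout) in self.spatial_intensities.items():
            if lin < 0 or lout < 0:
                problems.append(f"negative spatial intensity for {cls}")
        if problems:
            raise ValueError("invalid SynthConfig: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """Planted truth: per-clone table plus per-cell and spatial truth."""

    config: SynthConfig
    clones: pd.DataFrame
    cells: pd.DataFrame | None = None
    spatial: dict | None = None


# ---------------------------------------------------------------------------
# Sequence generation helpers


def _random_interior(rng, length) -> str:
    return "".join(rng.choice(list(AA), size=length, p=AA_FREQS))


def _unique_cdr3(rng, existing, prefixes, suffixes, motif=None) -> str:
    for _ in range(1000):
        interior = _random_interior(rng, rng.integers(4, 9))
        if motif is not None:
            pos = rng.integers(0, len(interior) + 1)
            interior = interior[:pos] + motif + interior[pos:]
        seq = prefixes[rng.integers(len(prefixes))] + interior + \
            suffixes[rng.integers(len(suffixes))]
        if seq not in existing:
            existing.add(seq)
            return seq
    raise RuntimeError("could not generate a unique CDR3")


def _reverse_translate(rng, aa: str) -> str:
    return "".join(CODONS[c][rng.integers(len(CODONS[c]))] for c in aa)


def _distinct_nucleotypes(rng, aa: str, n: int) -> list[str]:
    seen = set()
    while len(seen) < n:
        seen.add(_reverse_translate(rng, aa))
    return sorted(seen)


def zipf_abundances(n: int, exponent: float) -> np.ndarray:
    """Normalized Zipf law over ranks 1..n."""
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Bulk repertoires


def generate_repertoire_set(config: SynthConfig) -> tuple[dict, GroundTruth]:
    """Generate per-patient, per-tissue bulk repertoires with clone truth.

    Returns ``(repertoires, truth)`` where ``repertoires[(patient, tissue)]``
    is a :class:`~tilseq.repertoire.Repertoire` and ``truth.clones`` has one
    row per planted clone (abundance, pattern, nucleotypes, chains,
    phenotype, lineage, motif family, true per-tissue frequency).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    existing_aa, existing_tra = set(), set()
    clone_rows = []
    repertoires = {}
    family_assignment = []
    for fam, size in zip(config.motif_families, config.motif_family_sizes):
        family_assignment.extend([fam] * size)

    for p in range(config.n_patients):
        patient = f"P{p + 1:02d}"
        n = config.clones_per_patient
        abundance = zipf_abundances(n, config.zipf_exponent)
        patterns = rng.choice(PATTERNS, size=n, p=config.tissue_pattern_probs)
        lineages = np.where(rng.random(n) < config.cd8_clone_fraction, "CD8", "CD4")
        for i in range(n):
            # plant motif families into the first tumor-pattern clones of patient 1
            motif = None
            if p == 0 and family_assignment:
                motif = family_assignment.pop(0)
            aa = _unique_cdr3(rng, existing_aa, V_PREFIXES, J_SUFFIXES, motif)
            n_nt = 2 if rng.random() < config.convergence_rate else 1
            nts = _distinct_nucleotypes(rng, aa, n_nt)
            lineage = lineages[i]
            phen_pool = CD8_PHENOTYPES if lineage == "CD8" else CD4_PHENOTYPES
            clone_rows.append({
                "patient_id": patient, "clone_id": f"{patient}:C{i:05d}",
                "cdr3_aa": aa, "nucleotypes": nts,
                "tra_aa": _unique_cdr3(rng, existing_tra, TRA_PREFIXES, TRA_SUFFIXES),
                "abundance": abundance[i], "pattern": patterns[i],
                "lineage": lineage,
                "phenotype": phen_pool[rng.integers(len(phen_pool))],
                "motif_family": motif or "",
            })
    clones = pd.DataFrame(clone_rows)
    clones["tra_nt"] = [_reverse_translate(rng, aa) for aa in clones["tra_aa"]]

    for tissue in TISSUES:
        clones[f"true_freq_{tissue}"] = 0.0
    for patient, grp in clones.groupby("patient_id", sort=True):
        for tissue in TISSUES:
            member = grp["pattern"].map(lambda pat: tissue in PATTERN_TISSUES[pat])
            probs = grp.loc[member, "abundance"].to_numpy()
            if probs.size == 0:
                continue
            probs = probs / probs.sum()
            clones.loc[grp.index[member], f"true_freq_{tissue}"] = probs
            counts = rng.multinomial(config.depths[tissue], probs)
            rows = []
            for idx, total in zip(grp.index[member], counts):
                if total == 0:
                    continue
                clone = clones.loc[idx]
                nts = clone["nucleotypes"]
                if len(nts) == 1:
                    split = [total]
                else:
                    k = rng.binomial(total, 0.6)
                    split = [k, total - k]
                for nt, cnt in zip(nts, split):
                    if cnt == 0:
                        continue
                    rows.append({"cdr3_nt": nt, "cdr3_aa": clone["cdr3_aa"],
                                 "v_gene": "TRBV-SIM", "j_gene": "TRBJ-SIM",
                                 "read_count": int(cnt), "productive": True})
            # a small admixture of non-productive rearrangements
            n_bad = rng.binomial(len(rows), config.nonproductive_rate) if rows else 0
            for b in range(n_bad):
                aa_bad = "CASS" + _random_interior(rng, 3) + "*" + _random_interior(rng, 2)
                rows.append({"cdr3_nt": _reverse_translate(rng, aa_bad.replace("*", "W")),
                             "cdr3_aa": aa_bad, "v_gene": "TRBV-SIM",
                             "j_gene": "TRBJ-SIM",
                             "read_count": int(rng.integers(1, 50)),
                             "productive": False})
            data = pd.DataFrame(rows).sort_values(
                ["cdr3_aa", "cdr3_nt"], kind="mergesort").reset_index(drop=True)
            total_prod = data.loc[data["productive"], "read_count"].sum()
            data["frequency"] = np.where(
                data["productive"], data["read_count"] / total_prod, 0.0)
            repertoires[(patient, tissue)] = Repertoire(
                sample_id=f"{patient}_{tissue}", patient_id=patient,
                tissue=tissue, data=data)
    return repertoires, GroundTruth(config=config, clones=clones)


# ---------------------------------------------------------------------------
# Single-cell chains + expression


def _gene_universe(config: SynthConfig) -> list[str]:
    genes = ["CD4", "CD8A", "CD8B"]
    for markers in load_marker_table().values():
        genes.extend(markers)
    for gs in GENE_SETS.values():
        genes.extend(gs)
    genes = list(dict.fromkeys(genes))
    i = 1
    while len(genes) < config.n_genes:
        filler = f"GENE{i:04d}"
        if filler not in genes:
            genes.append(filler)
        i += 1
    return genes[:max(config.n_genes, len(genes))]


def generate_cells(config: SynthConfig, truth: GroundTruth) -> tuple[pd.DataFrame, AnnData, GroundTruth]:
    """Generate a contig table and an expression AnnData from clone truth.

    Cells are drawn from each tissue's true clone frequencies; a fraction
    ``both_chain_rate`` carries both chains (the rest TRB only); doublets
    (a second TRA/TRB pair from another clone) are injected at
    ``doublet_rate``; double-positive lineage is planted per tissue at
    ``dp_rate_by_tissue`` inside CD8 clones. Expression counts are Poisson
    draws from per-gene log-normal intensities with the cell's phenotype
    markers elevated ``marker_shift_fold``-fold and exhaustion genes of
    TUMOR-restricted clones shifted by ``exhaustion_shift`` ln-units.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    clones = truth.clones
    genes = _gene_universe(config)
    gene_idx = {g: i for i, g in enumerate(genes)}
    marker_table = load_marker_table()
    for markers in marker_table.values():
        missing = [g for g in markers if g not in gene_idx]
        if missing:
            raise ValueError(f"marker genes absent from gene universe: {missing}")

    base_mu = config.base_log_mean + rng.normal(0.0, 0.3, size=len(genes))
    for g in ("CD4", "CD8A", "CD8B"):
        base_mu[gene_idx[g]] = -10.0  # lineage genes are set explicitly below

    contig_rows, obs_rows, count_rows = [], [], []
    cell_no = 0
    for patient, grp in clones.groupby("patient_id", sort=True):
        for tissue in TISSUES:
            probs = grp[f"true_freq_{tissue}"].to_numpy()
            if probs.sum() == 0:
                continue
            probs = probs / probs.sum()
            picks = rng.choice(grp.index.to_numpy(), size=config.sc_cells_per_tissue,
                               p=probs)
            for idx in picks:
                clone = clones.loc[idx]
                cell_id = f"{patient}_{tissue}_cell{cell_no:06d}"
                cell_no += 1
                nts = clone["nucleotypes"]
                trb_nt = nts[rng.integers(len(nts))]
                has_tra = rng.random() < config.both_chain_rate
                contig_rows.append({"cell_id": cell_id, "chain": "TRB",
                                    "cdr3": clone["cdr3_aa"], "cdr3_nt": trb_nt})
                if has_tra:
                    contig_rows.append({"cell_id": cell_id, "chain": "TRA",
                                        "cdr3": clone["tra_aa"],
                                        "cdr3_nt": clone["tra_nt"]})
                is_doublet = rng.random() < config.doublet_rate and len(grp) > 1
                if is_doublet:
                    j = rng.integers(len(grp))
                    while grp.index[j] == idx:
                        j = rng.integers(len(grp))
                    other = clones.loc[grp.index[j]]
                    contig_rows.append({"cell_id": cell_id, "chain": "TRB",
                                        "cdr3": other["cdr3_aa"],
                                        "cdr3_nt": other["nucleotypes"][0]})
                    contig_rows.append({"cell_id": cell_id, "chain": "TRA",
                                        "cdr3": other["tra_aa"],
                                        "cdr3_nt": other["tra_nt"]})
                lineage = clone["lineage"]
                if lineage == "CD8" and rng.random() < config.dp_rate_by_tissue[tissue]:
                    lineage = "DP"
                obs_rows.append({"cell_id": cell_id, "patient_id": patient,
                                 "tissue": tissue, "clone_id": clone["clone_id"],
                                 "true_phenotype": clone["phenotype"],
                                 "true_lineage": lineage,
                                 "true_doublet": is_doublet,
                                 "has_tra": has_tra,
                                 "clone_pattern": clone["pattern"]})
                # expression
                mu = base_mu.copy()
                for g in marker_table[clone["phenotype"]]:
                    mu[gene_idx[g]] += np.log(config.marker_shift_fold)
                if clone["pattern"] == "TUMOR":
                    for g in GENE_SETS["exhaustion"]:
                        mu[gene_idx[g]] += config.exhaustion_shift
                lam = np.exp(mu + rng.normal(0.0, config.expr_noise_sd, size=len(genes)))
                counts = rng.poisson(lam)
                if lineage == "CD4":
                    counts[gene_idx["CD4"]] = 1 + rng.poisson(2)
                elif lineage == "CD8":
                    counts[gene_idx["CD8A"]] = 1 + rng.poisson(2)
                    counts[gene_idx["CD8B"]] = rng.poisson(1)
                else:  # DP
                    counts[gene_idx["CD4"]] = 1 + rng.poisson(1)
                    counts[gene_idx["CD8A"]] = 1 + rng.poisson(1)
                count_rows.append(counts)

    contigs = pd.DataFrame(contig_rows)
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    adata = AnnData(X=np.asarray(count_rows, dtype=np.int64), obs=obs,
                    var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    truth.cells = obs.reset_index()
    return contigs, adata, truth


# ---------------------------------------------------------------------------
# Spatial


def make_border(config: SynthConfig) -> BorderGeometry:
    w, h = config.spatial_domain_um
    mask = Polygon([(0, 0), (w, 0), (w, h), (0, h)])
    if config.border_shape == "straight":
        line = LineString([(w / 2, 0), (w / 2, h)])
        tumor = Polygon([(0, 0), (w / 2, 0), (w / 2, h), (0, h)])
    elif config.border_shape == "sine":
        ys = np.linspace(0, h, 201)
        xs = w / 2 + 0.1 * w * np.sin(2 * np.pi * ys / h)
        line = LineString(np.column_stack([xs, ys]))
        ring = [(x, y) for x, y in zip(xs, ys)] + [(0, h), (0, 0)]
        tumor = Polygon(ring)
    else:
        raise ValueError(f"unknown border_shape {config.border_shape!r}")
    return BorderGeometry(border=line, tumor_side=tumor, mask=mask)


def generate_spatial(config: SynthConfig) -> tuple[pd.DataFrame, BorderGeometry, dict]:
    """Inhomogeneous-Poisson mIHC cell table around a tumor border.

    Per marker class, inside/outside intensities (cells/mm²) drive Poisson
    point counts on each side; Ki67 positivity is Bernoulli per T cell;
    CAIX+ tumor cells fill the tumor side.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    border = make_border(config)
    outside = border.mask.difference(border.tumor_side)
    rows = []

    def _sample_points(poly, n):
        minx, miny, maxx, maxy = poly.bounds
        pts = np.empty((0, 2))
        from shapely import contains_xy
        while len(pts) < n:
            cand = np.column_stack([
                rng.uniform(minx, maxx, size=max(2 * n, 64)),
                rng.uniform(miny, maxy, size=max(2 * n, 64))])
            keep = cand[contains_xy(poly, cand[:, 0], cand[:, 1])]
            pts = np.vstack([pts, keep])
        return pts[:n]

    for cls, (lam_in, lam_out) in sorted(config.spatial_intensities.items()):
        for poly, lam in ((border.tumor_side, lam_in), (outside, lam_out)):
            n = rng.poisson(lam * poly.area / 1e6)
            for x, y in _sample_points(poly, n):
                rows.append({"x_um": x, "y_um": y, "CD3": True,
                             "CD4": cls == "CD4", "CD8": cls == "CD8",
                             "Ki67": bool(rng.random() < config.ki67_prob),
                             "CAIX": False})
    n_tumor = rng.poisson(config.caix_intensity * border.tumor_side.area / 1e6)
    for x, y in _sample_points(border.tumor_side, n_tumor):
        rows.append({"x_um": x, "y_um": y, "CD3": False, "CD4": False,
                     "CD8": False, "Ki67": bool(rng.random() < 0.05), "CAIX": True})
    cells = pd.DataFrame(rows)
    truth = {"intensities": dict(config.spatial_intensities),
             "ki67_prob": config.ki67_prob, "border_shape": config.border_shape}
    return cells, border, truth


# ---------------------------------------------------------------------------
# Control library / annotation db / public cohort


def generate_control_screen(config: SynthConfig, truth: GroundTruth,
                            n_background_per_donor: int = 50):
    """Expanded-clone set plus a donor-wise control library.

    Exactly ``round(patient_unique_rate * n_expanded)`` of the expanded
    tumor clones are withheld from every donor (planted patient-unique); the
    rest are planted into 1 + Binomial(n_donors − 1, 0.2) donors each.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    expanded = truth.clones.loc[truth.clones["true_freq_TUMOR"] > 0.01, "cdr3_aa"]
    expanded = sorted(expanded.unique())
    n_unique = int(round(config.patient_unique_rate * len(expanded)))
    order = rng.permutation(len(expanded))
    unique_set = {expanded[i] for i in order[:n_unique]}
    donors = [f"D{i + 1:03d}" for i in range(config.control_n_donors)]
    lib_rows = []
    existing = set(truth.clones["cdr3_aa"])
    for seq in expanded:
        if seq in unique_set:
            continue
        k = 1 + rng.binomial(config.control_n_donors - 1, 0.2)
        for d in rng.choice(donors, size=k, replace=False):
            lib_rows.append({"donor_id": d, "cdr3_aa": seq})
    for d in donors:
        for _ in range(n_background_per_donor):
            lib_rows.append({"donor_id": d,
                             "cdr3_aa": _unique_cdr3(rng, existing, V_PREFIXES,
                                                     J_SUFFIXES)})
    library = pd.DataFrame(lib_rows)
    planted = pd.DataFrame({"cdr3_aa": expanded,
                            "planted_unique": [s in unique_set for s in expanded]})
    return planted, library


def generate_annotation_db(config: SynthConfig, truth: GroundTruth,
                           n_hits: int = 5, n_decoys: int = 50) -> pd.DataFrame:
    """VDJdb-style table: a few planted case sequences plus decoy entries."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    pool = sorted(truth.clones["cdr3_aa"].unique())
    hits = [pool[i] for i in rng.choice(len(pool), size=min(n_hits, len(pool)),
                                        replace=False)]
    pathogens = ("CMV", "EBV", "InfluenzaA", "M.tuberculosis", "SARS-CoV-2")
    rows = [{"cdr3": s, "v": "TRBV-SIM", "j": "TRBJ-SIM",
             "antigen.epitope": f"EPITOPE{i:02d}",
             "antigen.species": pathogens[i % len(pathogens)]}
            for i, s in enumerate(hits)]
    existing = set(pool)
    for i in range(n_decoys):
        rows.append({"cdr3": _unique_cdr3(rng, existing, V_PREFIXES, J_SUFFIXES),
                     "v": "TRBV-SIM", "j": "TRBJ-SIM",
                     "antigen.epitope": f"DECOY{i:03d}",
                     "antigen.species": pathogens[i % len(pathogens)]})
    db = pd.DataFrame(rows).rename(columns={
        "cdr3": "cdr3_aa", "antigen.epitope": "antigen",
        "antigen.species": "species", "v": "v_gene", "j": "j_gene"})
    db.attrs["planted_hits"] = hits
    return db


def generate_public_cohort(seed: int, n_patients: int = 53, n_public: int = 4,
                           clones_per_patient: int = 60) -> tuple[pd.DataFrame, list[str]]:
    """Pooled per-patient tumor cell counts with planted public clonotypes.

    ``n_public`` sequences are planted in 10–14 patients with > 10 cells in
    at least one tumor; near-misses (too few patients, or never > 10 cells)
    plus private background clones exercise both thresholds.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    patients = [f"Q{i + 1:02d}" for i in range(n_patients)]
    existing = set()
    rows = []
    public = []
    for j in range(n_public):
        seq = _unique_cdr3(rng, existing, V_PREFIXES, J_SUFFIXES)
        public.append(seq)
        carriers = rng.choice(patients, size=int(rng.integers(10, 15)), replace=False)
        for i, p in enumerate(carriers):
            cells = int(rng.integers(11, 40)) if i == 0 else int(rng.integers(1, 30))
            rows.append({"patient_id": p, "key": seq, "cells": cells})
    # near-miss: shared widely but never reaching the cell bound
    near1 = _unique_cdr3(rng, existing, V_PREFIXES, J_SUFFIXES)
    for p in rng.choice(patients, size=12, replace=False):
        rows.append({"patient_id": p, "key": near1, "cells": int(rng.integers(1, 10))})
    # near-miss: many cells but too few patients
    near2 = _unique_cdr3(rng, existing, V_PREFIXES, J_SUFFIXES)
    for p in rng.choice(patients, size=5, replace=False):
        rows.append({"patient_id": p, "key": near2, "cells": int(rng.integers(11, 30))})
    for p in patients:
        for _ in range(clones_per_patient):
            rows.append({"patient_id": p,
                         "key": _unique_cdr3(rng, existing, V_PREFIXES, J_SUFFIXES),
                         "cells": int(rng.integers(1, 25))})
    return pd.DataFrame(rows), sorted(public)


# ---------------------------------------------------------------------------
# File emission


def write_bundle(config: SynthConfig, outdir) -> dict:
    """Generate everything and write the file bundle consumed by the readers.

    Emits immunoSEQ-style repertoire TSVs + a sample sheet, a contig TSV +
    MTX expression triplet + cell metadata, a spatial cell CSV + WKT
    geometry, a VDJdb-style annotation TSV, a control-library TSV, and the
    clone-level ground truth. Returns the path map.
    """
    from scipy.io import mmwrite

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reps, truth = generate_repertoire_set(config)
    sheet_rows = []
    for (patient, tissue), rep in sorted(reps.items()):
        path = out / f"repertoire_{patient}_{tissue}.tsv"
        df = rep.data
        pd.DataFrame({
            "nucleotide": df["cdr3_nt"], "aminoAcid": df["cdr3_aa"],
            "count": df["read_count"], "vGeneName": df["v_gene"],
            "jGeneName": df["j_gene"],
            "sequenceStatus": np.where(df["productive"], "In", "Out"),
        }).to_csv(path, sep="\t", index=False)
        sheet_rows.append({"sample_id": rep.sample_id, "patient_id": patient,
                           "tissue": tissue, "timepoint": "T0",
                           "path": path.name})
    pd.DataFrame(sheet_rows).to_csv(out / "samples.tsv", sep="\t", index=False)

    contigs, adata, truth = generate_cells(config, truth)
    contigs.to_csv(out / "contigs.tsv", sep="\t", index=False)
    from scipy import sparse
    mmwrite(str(out / "matrix.mtx"), sparse.csr_matrix(adata.X))
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.var_names).to_csv(out / "features.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(out / "cells.tsv", sep="\t")

    spatial_cells, border, spatial_truth = generate_spatial(config)
    spatial_cells.assign(**{m: spatial_cells[m].astype(int)
                            for m in ("CD3", "CD4", "CD8", "Ki67", "CAIX")}).to_csv(
        out / "spatial_cells.csv", index=False)
    (out / "border.wkt").write_text(json.dumps(border.to_wkt()))

    db = generate_annotation_db(config, truth)
    db.to_csv(out / "vdjdb.tsv", sep="\t", index=False)
    planted, library = generate_control_screen(config, truth)
    library.to_csv(out / "control_library.tsv", sep="\t", index=False)
    planted.to_csv(out / "planted_expanded.tsv", sep="\t", index=False)

    truth_clones = truth.clones.copy()
    truth_clones["nucleotypes"] = truth_clones["nucleotypes"].map(";".join)
    truth_clones.to_csv(out / "truth_clones.tsv", sep="\t", index=False)
    (out / "truth_params.json").write_text(
        json.dumps({**asdict(config), "spatial_truth": spatial_truth},
                   default=str, indent=2, sort_keys=True))
    return {"outdir": str(out), "n_samples": len(reps),
            "n_cells": int(adata.n_obs), "n_spatial_cells": int(len(spatial_cells))}
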