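"""Configuration-driven end-to-end execution.

``run_pipeline`` executes the analysis stages in dependency order —
repertoire → tracking → annotation → specificity → single cell → spatial —
skipping any stage whose inputs are absent from the config, writes one TSV
per stage output plus a ``summary.json`` of headline statistics, and is
deterministic for a fixed config (rerunning changes nothing but timestamps).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import repertoire as rep
from . import singlecell as sc
from . import spatial as sp
from . import specificity as spec
from . import tracking as trk
from .config import EXPANDED_THRESHOLD, GENE_SETS, load_marker_table

log = logging.getLogger("tilseq")

_TOP_KEYS = {"seed", "outdir", "inputs", "params", "log_level"}
_INPUT_KEYS = {"sample_sheet", "contigs", "expression_mtx", "expression_barcodes",
               "expression_features", "cells_meta", "spatial_cells", "border",
               "annotation_db", "control_library"}
_PARAM_KEYS = {"expanded_threshold", "size_class_bounds", "public_min_patients",
               "public_min_cells", "min_pct", "min_logfc", "profile_range_um",
               "profile_bin_um", "similarity_denominator", "top_n",
               "min_clonotypes", "min_fold", "hamming_radius", "marker_table"}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    bad_inputs = set(cfg.get("inputs", {}) or {}) - _INPUT_KEYS
    if bad_inputs:
        raise ConfigError(f"unknown input keys: {sorted(bad_inputs)}")
    bad_params = set(cfg.get("params", {}) or {}) - _PARAM_KEYS
    if bad_params:
        raise ConfigError(f"unknown param keys: {sorted(bad_params)}")
    if "outdir" not in cfg:
        raise ConfigError("config must set outdir")


def _load_repertoires(sheet_path):
    sheet = rep.read_sample_sheet(sheet_path)
    out = []
    for _, row in sheet.iterrows():
        r = rep.read_repertoire(row["path"], row["sample_id"], row["patient_id"],
                                row["tissue"], row.get("timepoint"))
        out.append(rep.filter_productive(r))
    return out


def run_pipeline(cfg: dict) -> dict:
    """Execute all stages whose inputs are present; return the summary dict."""
    validate_config(cfg)
    inputs = cfg.get("inputs", {}) or {}
    params = cfg.get("params", {}) or {}
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages_run": [], "stages_skipped": []}

    reps = None
    if inputs.get("sample_sheet"):
        summary["stages_run"].append("repertoire")
        reps = _load_repertoires(inputs["sample_sheet"])
        div = rep.diversity_table(reps)
        div.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        summary["clonality"] = {
            r["sample_id"]: round(r["clonality"], 6) for _, r in div.iterrows()}

        summary["stages_run"].append("tracking")
        pattern_totals = dict.fromkeys(trk.PATTERNS, 0)
        n_expanded = 0
        tracked_frames = []
        by_patient: dict[str, list] = {}
        for r in reps:
            by_patient.setdefault(r.patient_id, []).append(r)
        for patient in sorted(by_patient):
            tracked = trk.track_clonotypes(by_patient[patient])
            tracked.insert(0, "patient_id", patient)
            tracked_frames.append(tracked)
            for pat, cnt in trk.pattern_summary(tracked).items():
                pattern_totals[pat] += int(cnt)
            n_expanded += int(tracked["expanded_in_tumor"].sum())
        all_tracked = pd.concat(tracked_frames, ignore_index=True)
        all_tracked.to_csv(outdir / "tracked_clonotypes.tsv", sep="\t", index=False)
        summary["pattern_counts"] = pattern_totals
        summary["n_expanded_in_tumor"] = n_expanded
    else:
        summary["stages_skipped"].append("repertoire")
        summary["stages_skipped"].append("tracking")

    if reps is not None and (inputs.get("annotation_db") or inputs.get("control_library")):
        summary["stages_run"].append("annotation")
        tumor_reps = [r for r in reps if r.tissue == "TUMOR"]
        pooled = pd.concat(
            [r.productive.assign(sample_id=r.sample_id) for r in tumor_reps],
            ignore_index=True)
        if inputs.get("annotation_db"):
            db = ann.read_annotation_db(inputs["annotation_db"])
            hits, _ = ann.match_database(pooled, db)
            hits.to_csv(outdir / "annotation_hits.tsv", sep="\t", index=False)
            summary["annotated_unique_fraction"] = round(
                ann.annotated_unique_fraction(pooled, db), 6)
        if inputs.get("control_library"):
            lib = ann.read_control_library(inputs["control_library"])
            thr = params.get("expanded_threshold", EXPANDED_THRESHOLD)
            expanded = pooled.loc[pooled["frequency"] > thr, "cdr3_aa"].unique()
            screen = ann.screen_control_library(expanded, lib)
            screen.to_csv(outdir / "control_screen.tsv", sep="\t", index=False)
            if len(screen):
                summary["patient_unique_fraction"] = round(
                    float(screen["patient_unique"].mean()), 6)
    else:
        summary["stages_skipped"].append("annotation")

    if reps is not None:
        summary["stages_run"].append("specificity")
        group_means = {}
        for tissue in ("TUMOR", "NAT", "PBMC"):
            tissue_reps = [r for r in reps if r.tissue == tissue]
            if not tissue_reps:
                continue
            seqs = set()
            for r in tissue_reps:
                seqs.update(rep.top_n(r, params.get("top_n", 120))["cdr3_aa"])
            motifs = spec.mine_motifs(
                seqs, min_clonotypes=params.get("min_clonotypes", 3))
            groups = spec.build_groups(
                seqs, motifs, hamming_radius=params.get("hamming_radius", 1))
            group_means[tissue] = round(
                float(np.mean([g.size for g in groups])), 6)
        summary["mean_specificity_group_size"] = group_means
    else:
        summary["stages_skipped"].append("specificity")

    if inputs.get("contigs"):
        summary["stages_run"].append("single_cell")
        contigs = sc.load_contigs(inputs["contigs"])
        kept, n_doublets = sc.filter_doublets(contigs)
        cells = sc.pair_chains(kept)
        summary["n_cells"] = int(contigs["cell_id"].nunique())
        summary["n_doublets_removed"] = n_doublets
        summary["n_paired_cells"] = int(cells["paired"].sum())
        if inputs.get("cells_meta"):
            meta = pd.read_csv(inputs["cells_meta"], sep="\t")
            cells = cells.merge(meta, on="cell_id", how="left")
        adata = None
        if inputs.get("expression_mtx"):
            from scipy.io import mmread
            from anndata import AnnData
            x = np.asarray(mmread(inputs["expression_mtx"]).todense())
            barcodes = pd.read_csv(inputs["expression_barcodes"], header=None)[0]
            features = pd.read_csv(inputs["expression_features"], header=None)[0]
            adata = AnnData(X=x, obs=pd.DataFrame(index=barcodes.astype(str)),
                            var=pd.DataFrame(index=features.astype(str)))
            sc.normalize(adata)
            lineage = sc.assign_lineage(adata)
            summary["dp_fraction"] = round(float((lineage == "DP").mean()), 6)
            marker_table = load_marker_table(params.get("marker_table"))
            phen = sc.classify_phenotype(adata, marker_table)
            cells = cells.merge(lineage.rename("lineage"), left_on="cell_id",
                                right_index=True, how="left")
            cells = cells.merge(phen["phenotype"], left_on="cell_id",
                                right_index=True, how="left")
            for name, genes in GENE_SETS.items():
                score = sc.score_gene_set(adata, genes)
                summary[f"mean_{name}_score"] = round(float(score.mean()), 6)
        clono = sc.clonotype_table(cells)
        clono_out = clono.drop(columns=[c for c in ("lineage_composition",
                                                    "phenotype_composition")
                                        if c in clono.columns])
        clono_out.to_csv(outdir / "clonotypes.tsv", sep="\t", index=False)
        cells.to_csv(outdir / "cell_annotations.tsv", sep="\t", index=False)
        density = sc.clonotype_density(clono)
        summary["clonotype_density"] = {k: round(float(v), 6)
                                        for k, v in density.items()}
    else:
        summary["stages_skipped"].append("single_cell")

    if inputs.get("spatial_cells") and inputs.get("border"):
        summary["stages_run"].append("spatial")
        cells_sp = sp.load_cell_table(inputs["spatial_cells"])
        wkts = json.loads(Path(inputs["border"]).read_text())
        border = sp.BorderGeometry.from_wkt(wkts["border"], wkts["tumor_side"],
                                            wkts["mask"])
        profiles = []
        calls = {}
        for cls in ("CD8", "CD4"):
            prof = sp.density_profile(
                cells_sp, border, marker_class=cls,
                bin_width=params.get("profile_bin_um", 50.0),
                profile_range=params.get("profile_range_um", 500.0))
            profiles.append(prof)
            calls[cls] = sp.classify_infiltration(prof)
        pd.concat(profiles, ignore_index=True).to_csv(
            outdir / "density_profiles.tsv", sep="\t", index=False)
        summary["infiltration_calls"] = calls
        summary["ki67_fraction"] = {
            cls: round(sp.ki67_fraction(cells_sp, cls)["fraction"], 6)
            for cls in ("CD8", "CD4")}
    else:
        summary["stages_skipped"].append("spatial")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
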