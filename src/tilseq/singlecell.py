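"""Single-cell V(D)J + expression integration.

Cells arrive as a 10X-style contig table (one row per recovered chain) plus a
cells × genes count matrix (`anndata.AnnData`). The module pairs TRA/TRB
chains into cell-level clonotype keys, removes putative doublets (more than
one pair of chains), classifies clone sizes (singleton / 2–4 / 5–20 / >20
cells), assigns CD4/CD8/double-positive lineage from raw co-receptor counts,
classifies phenotypes with a marker-score argmax, scores functional gene
sets, finds per-cluster marker genes (Wilcoxon rank-sum with min.pct and
log-fold-change thresholds, BH-adjusted), and reconciles single-cell clonal
frequencies with bulk DNA-based repertoire frequencies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .config import MIN_LOGFC, MIN_PCT, SIZE_CLASS_BOUNDS, resolve_gene
from .tracking import classify_tissue_pattern

PAIR_SEP = "|"


# ---------------------------------------------------------------------------
# Chain pairing and doublet filtering


def load_contigs(path) -> pd.DataFrame:
    """Read a filtered-contig-style TSV (cell_id, chain, cdr3, cdr3_nt, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"cell_id", "chain", "cdr3"}
    if not needed <= set(df.columns):
        raise ValueError(f"contig table needs columns {sorted(needed)}")
    if "cdr3_nt" not in df.columns:
        df["cdr3_nt"] = None
    return df


def filter_doublets(contigs: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove cells with more than one distinct TRA or TRB CDR3.

    Returns the retained contig rows and the number of removed cells.
    """
    per_cell = (contigs.drop_duplicates(["cell_id", "chain", "cdr3"])
                .groupby(["cell_id", "chain"])["cdr3"].nunique().unstack(fill_value=0))
    doublet_cells = per_cell.index[(per_cell >= 2).any(axis=1)]
    kept = contigs[~contigs["cell_id"].isin(doublet_cells)]
    return kept.reset_index(drop=True), int(len(doublet_cells))


def pair_chains(contigs: pd.DataFrame) -> pd.DataFrame:
    """Assign TRA/TRB pair keys to cells with exactly one chain of each kind.

    Returns one row per cell: tra/trb CDR3 aa + nt, ``n_tra``/``n_trb`` and
    ``paired``. Unpaired cells (missing a chain) are retained with
    ``paired=False`` for expression-only summaries.
    """
    uniq = contigs.drop_duplicates(["cell_id", "chain", "cdr3"])
    agg = (uniq.groupby(["cell_id", "chain"])
           .agg(n=("cdr3", "size"), aa=("cdr3", "first"), nt=("cdr3_nt", "first"))
           .unstack("chain"))
    out = pd.DataFrame(index=agg.index)
    for chain in ("TRA", "TRB"):
        low = chain.lower()
        n = agg.get(("n", chain))
        out[f"n_{low}"] = (n.fillna(0).astype(int) if n is not None else 0)
        out[f"{low}_aa"] = agg.get(("aa", chain))
        out[f"{low}_nt"] = agg.get(("nt", chain))
    out["paired"] = (out["n_tra"] == 1) & (out["n_trb"] == 1)
    out["pair_key"] = np.where(out["paired"],
                               out["tra_aa"].astype(str) + PAIR_SEP
                               + out["trb_aa"].astype(str), None)
    unpaired = ~out["paired"]
    for col in ("tra_aa", "trb_aa", "tra_nt", "trb_nt"):
        out.loc[unpaired, col] = None
    return out.reset_index().sort_values("cell_id", kind="mergesort",
                                         ignore_index=True)


# ---------------------------------------------------------------------------
# Clone sizes


def assign_size_class(cell_count: int) -> str:
    """Clone-size class: 1 → singleton, 2–4 → small, 5–20 → medium, >20 → large."""
    if cell_count < 1:
        raise ValueError("cell_count must be >= 1")
    small, medium, large = SIZE_CLASS_BOUNDS
    if cell_count < small:
        return "singleton"
    if cell_count < medium:
        return "small"
    if cell_count < large:
        return "medium"
    return "large"


def clonotype_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Aggregate paired cells into unique TRA/TRB clonotypes.

    ``cells`` must have ``pair_key`` (non-null for paired cells) and may have
    ``tissue`` / ``patient_id`` / ``lineage`` / ``phenotype`` columns, which
    are summarized per clonotype (tissue pattern, lineage and phenotype
    composition).
    """
    paired = cells[cells["pair_key"].notna()]
    rows = []
    for key, grp in paired.groupby("pair_key", sort=True):
        n = len(grp)
        row = {"pair_key": key, "cell_count": n,
               "size_class": assign_size_class(n), "multiplet": n >= 2}
        if "tissue" in grp.columns:
            row["pattern"] = classify_tissue_pattern(set(grp["tissue"]))
            for t in sorted(set(grp["tissue"])):
                row[f"cells_{t}"] = int((grp["tissue"] == t).sum())
        if "lineage" in grp.columns:
            comp = grp["lineage"].value_counts().to_dict()
            row["lineage_composition"] = comp
            row["n_dp"] = int(comp.get("DP", 0))
        if "phenotype" in grp.columns:
            row["phenotype_composition"] = grp["phenotype"].value_counts().to_dict()
        rows.append(row)
    out = pd.DataFrame(rows)
    for col in [c for c in out.columns if c.startswith("cells_")]:
        out[col] = out[col].fillna(0).astype(int)
    return out


def clonotype_density(clonotypes: pd.DataFrame) -> pd.Series:
    """Fraction of unique clonotypes in each size class (sums to 1)."""
    counts = clonotypes["size_class"].value_counts()
    counts = counts.reindex(["singleton", "small", "medium", "large"], fill_value=0)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Expression: normalization, lineage, phenotype, gene sets


def _dense(x) -> np.ndarray:
    return x.toarray() if sparse.issparse(x) else np.asarray(x)


def normalize(adata: AnnData, target_sum: float = 1e4) -> AnnData:
    """Library-size normalize to ``target_sum`` counts/cell, then log1p.

    Stores the result in ``layers['lognorm']`` and leaves raw counts in X.
    """
    counts = _dense(adata.X).astype(float)
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    adata.layers["lognorm"] = np.log1p(counts / lib * target_sum)
    return adata


def _gene_counts(adata: AnnData, genes) -> np.ndarray:
    present = [g for g in genes if g in adata.var_names]
    if not present:
        return np.zeros(adata.n_obs)
    idx = [adata.var_names.get_loc(g) for g in present]
    return _dense(adata.X)[:, idx].sum(axis=1)


def assign_lineage(adata: AnnData, cd4_genes=("CD4",), cd8_genes=("CD8A", "CD8B"),
                   min_count: int = 1) -> pd.Series:
    """CD4 / CD8 / DP / unassigned per cell, from raw co-receptor counts.

    CD4 ⇔ summed CD4 counts ≥ ``min_count`` and CD8 counts < ``min_count``;
    CD8 symmetric; DP when both clear the threshold; unassigned otherwise.
    """
    cd4 = _gene_counts(adata, cd4_genes) >= min_count
    cd8 = _gene_counts(adata, cd8_genes) >= min_count
    lineage = np.where(cd4 & cd8, "DP",
                       np.where(cd4, "CD4", np.where(cd8, "CD8", "unassigned")))
    return pd.Series(lineage, index=adata.obs_names, name="lineage")


def classify_phenotype(adata: AnnData, marker_table: dict[str, list[str]],
                       min_score_margin: float = 0.05) -> pd.DataFrame:
    """Marker-score phenotype assignment.

    Score(phenotype) = mean z-scaled log-normalized expression over its
    markers; the argmax label is assigned when it beats the runner-up by
    ``min_score_margin``, otherwise 'unassigned'. Markers absent from the
    matrix are dropped with a warning; a phenotype with no present markers
    never wins.
    """
    if "lognorm" not in adata.layers:
        normalize(adata)
    x = np.asarray(adata.layers["lognorm"], float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    scores = {}
    for phenotype, genes in marker_table.items():
        genes = [resolve_gene(g) for g in genes]
        present = [g for g in genes if g in adata.var_names]
        missing = set(genes) - set(present)
        if missing:
            warnings.warn(f"{phenotype}: markers absent from matrix: {sorted(missing)}",
                          stacklevel=2)
        if not present:
            scores[phenotype] = np.full(adata.n_obs, -np.inf)
            continue
        idx = [adata.var_names.get_loc(g) for g in present]
        scores[phenotype] = z[:, idx].mean(axis=1)
    score_df = pd.DataFrame(scores, index=adata.obs_names)
    arr = score_df.to_numpy()
    order = np.argsort(arr, axis=1)
    best = arr[np.arange(len(arr)), order[:, -1]]
    runner = arr[np.arange(len(arr)), order[:, -2]] if arr.shape[1] > 1 else -np.inf
    labels = score_df.columns.to_numpy()[order[:, -1]]
    nonempty = _dense(adata.X).sum(axis=1) > 0
    labels = np.where(nonempty & np.isfinite(best)
                      & (best - runner >= min_score_margin),
                      labels, "unassigned")
    score_df["phenotype"] = labels
    return score_df


def score_gene_set(adata: AnnData, genes, groupby: str | None = None):
    """Mean log-normalized expression of a gene set per cell.

    Without ``groupby`` returns the per-cell score Series. With a ``groupby``
    obs column, additionally returns group mean ± SD and Welch t statistics
    for every group pair.
    """
    if "lognorm" not in adata.layers:
        normalize(adata)
    genes = [resolve_gene(g) for g in genes]
    present = [g for g in genes if g in adata.var_names]
    if not present:
        raise ValueError("gene set has no genes in the expression matrix")
    idx = [adata.var_names.get_loc(g) for g in present]
    score = pd.Series(np.asarray(adata.layers["lognorm"])[:, idx].mean(axis=1),
                      index=adata.obs_names, name="score")
    if groupby is None:
        return score
    groups = adata.obs[groupby]
    summary = score.groupby(groups, observed=True).agg(["mean", "std", "count"])
    labels = sorted(summary.index)
    contrasts = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            sa, sb = score[groups == a], score[groups == b]
            if len(sa) > 1 and len(sb) > 1:
                t, p = stats.ttest_ind(sa, sb, equal_var=False)
            else:
                t, p = np.nan, np.nan
            contrasts.append({"group_a": a, "group_b": b, "t_stat": float(t),
                              "p_value": float(p)})
    return score, summary, pd.DataFrame(contrasts)


# ---------------------------------------------------------------------------
# Marker finding


def find_markers(adata: AnnData, groupby: str, min_pct: float = MIN_PCT,
                 min_logfc: float = MIN_LOGFC, fdr: float | None = None) -> pd.DataFrame:
    """Per-cluster marker genes, each cluster against the rest.

    A gene is a candidate marker for a cluster when it is expressed
    (count > 0) in ≥ ``min_pct`` of the cluster's cells and the natural-log
    fold-change of mean expression (Seurat-style, on expm1 of the
    log-normalized layer, pseudocount 1e-9) is ≥ ``min_logfc`` in absolute
    value. Candidates are tested with a Wilcoxon rank-sum test and BH
    corrected per cluster. Clusters with < 3 cells are skipped.
    """
    if "lognorm" not in adata.layers:
        normalize(adata)
    x = np.asarray(adata.layers["lognorm"], float)
    raw = _dense(adata.X)
    groups = adata.obs[groupby]
    results = []
    for cluster in sorted(groups.unique()):
        mask = (groups == cluster).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"cluster {cluster!r} has <3 cells; skipped", stacklevel=2)
            continue
        xin, xout = x[mask], x[~mask]
        pct_in = (raw[mask] > 0).mean(axis=0)
        pct_out = (raw[~mask] > 0).mean(axis=0)
        eps = 1e-9
        logfc = np.log(np.expm1(xin).mean(axis=0) + eps) - \
            np.log(np.expm1(xout).mean(axis=0) + eps)
        keep = (pct_in >= min_pct) & (np.abs(logfc) >= min_logfc)
        idx = np.where(keep)[0]
        if idx.size == 0:
            continue
        pvals = np.empty(idx.size)
        for j, g in enumerate(idx):
            pvals[j] = stats.mannwhitneyu(xin[:, g], xout[:, g],
                                          alternative="two-sided").pvalue
        padj = multipletests(pvals, method="fdr_bh")[1]
        df = pd.DataFrame({
            "cluster": cluster,
            "gene": adata.var_names[idx],
            "logfc": logfc[idx],
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
            "p_value": pvals,
            "p_adj": padj,
        })
        results.append(df.sort_values(["p_adj", "p_value", "gene"], kind="mergesort"))
    if not results:
        return pd.DataFrame(columns=["cluster", "gene", "logfc", "pct_in",
                                     "pct_out", "p_value", "p_adj"])
    out = pd.concat(results, ignore_index=True)
    if fdr is not None:
        out = out[out["p_adj"] < fdr].reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Bulk vs single-cell reconciliation


def correlate_bulk_sc(bulk_freq: pd.Series, cells: pd.DataFrame,
                      min_matches: int = 5) -> dict:
    """Pearson correlation of bulk and single-cell clonal frequencies.

    ``bulk_freq`` maps TRB CDR3 aa → bulk frequency; single-cell frequencies
    are cell fractions per unique TRB among paired cells. Reports r on raw
    and on log10 frequencies plus matched/unmatched counts; raises when
    fewer than ``min_matches`` clonotypes match.
    """
    paired = cells[cells["pair_key"].notna()]
    sc_freq = paired.groupby("trb_aa").size() / len(paired)
    matched = sc_freq.index.intersection(bulk_freq.index)
    if len(matched) < min_matches:
        raise ValueError(f"only {len(matched)} matched clonotypes (< {min_matches})")
    b = bulk_freq.loc[matched].to_numpy(float)
    s = sc_freq.loc[matched].to_numpy(float)
    r_raw = float(stats.pearsonr(b, s).statistic)
    r_log = float(stats.pearsonr(np.log10(b), np.log10(s)).statistic)
    return {"r": r_raw, "r_log10": r_log, "n_matched": int(len(matched)),
            "n_bulk_only": int(len(bulk_freq.index.difference(sc_freq.index))),
            "n_sc_only": int(len(sc_freq.index.difference(bulk_freq.index)))}


def dp_clonotype_analysis(clonotypes: pd.DataFrame) -> pd.DataFrame:
    """Summarize clonotypes that contain CD4+CD8+ double-positive cells.

    Input is a `clonotype_table` output with ``lineage_composition``. Flags
    clonotypes whose *every* cell is DP ('DP-only'); per-pattern counts of
    DP-containing clonotypes are available via ``groupby('pattern')``.
    """
    has = clonotypes[clonotypes.get("n_dp", 0) > 0].copy()
    if has.empty:
        return has
    has["n_single_positive"] = has["lineage_composition"].map(
        lambda c: int(c.get("CD4", 0) + c.get("CD8", 0)))
    has["dp_only"] = has["n_single_positive"] == 0
    return has.reset_index(drop=True)
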