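"""Chain pairing, clone sizes, lineage/phenotype assignment, markers, bulk-sc."""

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from tilseq.config import GENE_SETS, load_marker_table
from tilseq.singlecell import (assign_lineage, assign_size_class,
                               classify_phenotype, clonotype_density,
                               clonotype_table, correlate_bulk_sc,
                               dp_clonotype_analysis, filter_doublets,
                               find_markers, normalize, pair_chains,
                               score_gene_set)


def _contigs(rows):
    return pd.DataFrame(rows, columns=["cell_id", "chain", "cdr3", "cdr3_nt"])


class TestPairing:
    def test_single_tra_trb_cell_gets_pair_key(self):
        cells = pair_chains(_contigs([
            ("c1", "TRA", "CAVHNTDKLIF", "TGTA"),
            ("c1", "TRB", "CASSPGQGGGYTF", "TGTB")]))
        assert cells["pair_key"].iloc[0] == "CAVHNTDKLIF|CASSPGQGGGYTF"
        assert bool(cells["paired"].iloc[0])

    def test_trb_only_cell_is_unpaired_but_retained(self):
        cells = pair_chains(_contigs([("c1", "TRB", "CASSA", "TGT")]))
        assert not bool(cells["paired"].iloc[0])
        assert cells["pair_key"].iloc[0] is None

    def test_planted_both_chain_cells_all_pair(self, default_cells):
        cfg, contigs, adata, truth = default_cells
        kept, _ = filter_doublets(contigs)
        cells = pair_chains(kept)
        planted = truth.cells.set_index("cell_id")
        retained = planted.loc[cells["cell_id"]]
        expect = (retained["has_tra"] & ~retained["true_doublet"]).sum()
        assert cells["paired"].sum() == expect


class TestDoublets:
    def test_cell_with_two_trb_chains_removed(self):
        kept, n = filter_doublets(_contigs([
            ("c1", "TRB", "CASSA", "T1"), ("c1", "TRB", "CASSG", "T2"),
            ("c2", "TRA", "CAVA", "T3"), ("c2", "TRB", "CASST", "T4")]))
        assert n == 1 and set(kept["cell_id"]) == {"c2"}

    def test_single_pair_cell_retained(self):
        kept, n = filter_doublets(_contigs([
            ("c1", "TRA", "CAVA", "T1"), ("c1", "TRB", "CASSA", "T2")]))
        assert n == 0 and len(kept) == 2

    def test_planted_doublet_rate_recovered_within_binomial_ci(self, default_cells):
        cfg, contigs, adata, truth = default_cells
        _, removed = filter_doublets(contigs)
        n = len(truth.cells)
        rate = removed / n
        se = np.sqrt(cfg.doublet_rate * (1 - cfg.doublet_rate) / n)
        assert abs(rate - cfg.doublet_rate) < 4 * se


class TestSizeClasses:
    @pytest.mark.parametrize("count,expected", [
        (1, "singleton"), (2, "small"), (4, "small"),
        (5, "medium"), (20, "medium"), (21, "large"),
    ])
    def test_boundary_table(self, count, expected):
        assert assign_size_class(count) == expected

    def test_density_fractions(self):
        clono = pd.DataFrame({"size_class": ["large"] * 2 + ["singleton"] * 8})
        dens = clonotype_density(clono)
        assert dens["large"] == pytest.approx(0.2)
        assert dens.sum() == pytest.approx(1.0)

    def test_all_singletons(self):
        dens = clonotype_density(pd.DataFrame({"size_class": ["singleton"] * 5}))
        assert dens["singleton"] == 1.0


def _adata(counts, genes, obs=None):
    return AnnData(X=np.asarray(counts, dtype=float),
                   obs=obs if obs is not None else pd.DataFrame(
                       index=[f"c{i}" for i in range(len(counts))]),
                   var=pd.DataFrame(index=pd.Index(genes, name="gene")))


class TestLineage:
    def test_rules(self):
        ad = _adata([[3, 0, 0], [2, 4, 0], [0, 1, 1], [0, 0, 0]],
                    ["CD4", "CD8A", "CD8B"])
        assert assign_lineage(ad).tolist() == ["CD4", "DP", "CD8", "unassigned"]

    def test_partition_into_four_labels(self, default_cells):
        _, _, adata, truth = default_cells
        lineage = assign_lineage(adata)
        assert set(lineage.unique()) <= {"CD4", "CD8", "DP", "unassigned"}
        assert len(lineage) == adata.n_obs

    def test_planted_dp_fraction_recovered(self, default_cells):
        cfg, _, adata, truth = default_cells
        lineage = assign_lineage(adata)
        planted = (truth.cells["true_lineage"] == "DP").mean()
        assert abs((lineage == "DP").mean() - planted) < 0.003


class TestPhenotype:
    def test_all_zero_cell_unassigned(self):
        mt = {"A": ["G1"], "B": ["G2"]}
        ad = _adata([[5, 0], [0, 0]], ["G1", "G2"])
        normalize(ad)
        out = classify_phenotype(ad, mt, min_score_margin=0.05)
        assert out["phenotype"].iloc[1] == "unassigned"

    def test_naive_marker_cell_gets_naive_like_label(self):
        mt = {"naive": ["IL7R", "LTB"], "T_eff": ["GZMB", "PRF1"]}
        counts = [[50, 40, 0, 0], [0, 0, 50, 40], [50, 45, 2, 1]]
        ad = _adata(counts, ["IL7R", "LTB", "GZMB", "PRF1"])
        out = classify_phenotype(ad, mt)
        assert out["phenotype"].iloc[0] == "naive"
        assert out["phenotype"].iloc[1] == "T_eff"
        assert out["phenotype"].iloc[2] == "naive"

    def test_absent_markers_warn(self):
        ad = _adata([[1.0]], ["G1"])
        with pytest.warns(UserWarning):
            classify_phenotype(ad, {"A": ["G1"], "B": ["NOPE"]})

    def test_planted_phenotypes_recovered_at_twofold_elevation(self, default_cells):
        cfg, _, adata, truth = default_cells
        assert cfg.marker_shift_fold == 2.0
        out = classify_phenotype(adata, load_marker_table())
        truth_lbl = truth.cells.set_index("cell_id")["true_phenotype"]
        acc = (out.loc[truth_lbl.index, "phenotype"] == truth_lbl).mean()
        assert acc >= 0.90

    def test_recovery_degrades_monotonically_with_noise(self):
        from tilseq.simulate import (SynthConfig, generate_cells,
                                     generate_repertoire_set)
        accs = []
        for sd in (0.2, 0.8, 1.6):
            cfg = SynthConfig(seed=21, n_patients=1, clones_per_patient=200,
                              sc_cells_per_tissue=300, expr_noise_sd=sd)
            _, truth = generate_repertoire_set(cfg)
            _, ad, truth = generate_cells(cfg, truth)
            out = classify_phenotype(ad, load_marker_table())
            lbl = truth.cells.set_index("cell_id")["true_phenotype"]
            accs.append((out.loc[lbl.index, "phenotype"] == lbl).mean())
        assert accs[0] > accs[1] > accs[2]


class TestGeneSetScore:
    def test_mean_of_normalized_values(self):
        ad = _adata([[1.0, 2.0, 3.0]], ["GZMB", "PRF1", "IFNG"])
        ad.layers["lognorm"] = np.array([[1.0, 2.0, 3.0]])
        score = score_gene_set(ad, ["GZMB", "PRF1", "IFNG"])
        assert score.iloc[0] == pytest.approx(2.0)

    def test_identical_groups_have_near_zero_t(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(5, size=(200, 3)).astype(float)
        obs = pd.DataFrame({"grp": ["A"] * 100 + ["B"] * 100},
                           index=[f"c{i}" for i in range(200)])
        ad = _adata(x, ["GZMB", "PRF1", "IFNG"], obs)
        _, _, contrasts = score_gene_set(ad, ["GZMB", "PRF1", "IFNG"], groupby="grp")
        assert abs(contrasts["t_stat"].iloc[0]) < 2.0

    def test_exhaustion_elevated_in_tumor_restricted_clones(self, default_cells):
        cfg, _, adata, truth = default_cells
        adata.obs["clone_pattern"] = truth.cells.set_index("cell_id").loc[
            adata.obs_names, "clone_pattern"]
        sub = adata[adata.obs["clone_pattern"].isin(["TUMOR", "ALL"])].copy()
        _, _, contrasts = score_gene_set(sub, GENE_SETS["exhaustion"],
                                         groupby="clone_pattern")
        row = contrasts.set_index(["group_a", "group_b"]).loc[("ALL", "TUMOR")]
        assert row["t_stat"] < 0 and row["p_value"] < 0.01

    def test_empty_intersection_is_an_error(self):
        ad = _adata([[1.0]], ["G1"])
        with pytest.raises(ValueError):
            score_gene_set(ad, ["NOPE"])


class TestFindMarkers:
    def _planted(self, rng, n_cells=120, n_genes=100, n_marked=20, fold=4.0):
        base = rng.poisson(5, size=(2 * n_cells, n_genes)).astype(float)
        base[:n_cells, :n_marked] = rng.poisson(5 * fold, size=(n_cells, n_marked))
        obs = pd.DataFrame({"cluster": ["A"] * n_cells + ["B"] * n_cells},
                           index=[f"c{i}" for i in range(2 * n_cells)])
        genes = [f"MK{i:02d}" for i in range(n_marked)] + \
            [f"BG{i:02d}" for i in range(n_genes - n_marked)]
        return _adata(base, genes, obs)

    def test_planted_cluster_genes_recovered_at_fdr(self):
        ad = self._planted(np.random.default_rng(1))
        out = find_markers(ad, "cluster", fdr=0.05)
        up_a = out[(out["cluster"] == "A") & (out["logfc"] > 0)]["gene"]
        hits = sum(g.startswith("MK") for g in up_a)
        assert hits >= 18

    def test_low_pct_gene_excluded(self):
        rng = np.random.default_rng(2)
        x = np.zeros((100, 2))
        x[:, 1] = rng.poisson(5, 100)
        x[:5, 0] = 50.0  # expressed in 10% of cluster A
        obs = pd.DataFrame({"cluster": ["A"] * 50 + ["B"] * 50},
                           index=[f"c{i}" for i in range(100)])
        ad = _adata(x, ["RARE", "COMMON"], obs)
        out = find_markers(ad, "cluster")
        assert "RARE" not in set(out["gene"])

    def test_tiny_cluster_skipped_with_warning(self):
        obs = pd.DataFrame({"cluster": ["A"] * 2 + ["B"] * 20},
                           index=[f"c{i}" for i in range(22)])
        ad = _adata(np.random.default_rng(3).poisson(5, (22, 4)), list("WXYZ"), obs)
        with pytest.warns(UserWarning):
            find_markers(ad, "cluster")

    def test_agrees_with_scanpy_wilcoxon(self):
        import scanpy as scp
        ad = self._planted(np.random.default_rng(4))
        out = find_markers(ad, "cluster", fdr=0.05)
        ours = set(out[(out["cluster"] == "A") & (out["logfc"] > 0)]["gene"])

        ad2 = ad.copy()
        scp.pp.normalize_total(ad2, target_sum=1e4)
        scp.pp.log1p(ad2)
        scp.tl.rank_genes_groups(ad2, "cluster", method="wilcoxon", pts=True)
        df = scp.get.rank_genes_groups_df(ad2, group="A")
        theirs = set(df[(df["pvals_adj"] < 0.05) & (df["logfoldchanges"] > 0.25 / np.log(2))
                        & (df["pct_nz_group"] >= 0.25)]["names"])
        marked = {g for g in ours | theirs if g.startswith("MK")}
        assert marked and (ours & theirs) >= marked


class TestBulkScCorrelation:
    def test_identical_frequencies_give_r_one(self):
        cells = pd.DataFrame({
            "pair_key": ["a|A"] * 4 + ["b|B"] * 3 + ["c|C"] * 2 + ["d|D", "e|E"],
            "trb_aa": list("AAAABBBCCDE")})
        sc_freq = cells.groupby("trb_aa").size() / len(cells)
        out = correlate_bulk_sc(sc_freq, cells)
        assert out["r"] == pytest.approx(1.0)

    def test_permuted_frequencies_decorrelate(self):
        rng = np.random.default_rng(6)
        n = 100
        keys = [f"K{i:03d}" for i in range(n)]
        counts = rng.multinomial(2000, np.full(n, 1 / n) * 0 + np.linspace(1, 2, n) / np.linspace(1, 2, n).sum())
        cells = pd.DataFrame({
            "trb_aa": np.repeat(keys, counts),
            "pair_key": np.repeat([f"a|{k}" for k in keys], counts)})
        bulk = pd.Series(rng.permutation(counts) / counts.sum(), index=keys)
        out = correlate_bulk_sc(bulk, cells)
        assert abs(out["r"]) < 0.2

    def test_too_few_matches_is_an_error(self):
        cells = pd.DataFrame({"pair_key": ["a|A"], "trb_aa": ["A"]})
        with pytest.raises(ValueError):
            correlate_bulk_sc(pd.Series({"A": 1.0}), cells)


class TestDpClonotypes:
    def _cells(self, spec):
        rows = []
        for key, (lineages, tissues) in spec.items():
            for i, (lin, tis) in enumerate(zip(lineages, tissues)):
                rows.append({"cell_id": f"{key}{i}", "pair_key": key,
                             "lineage": lin, "tissue": tis})
        return pd.DataFrame(rows)

    def test_mixed_lineage_clonotype_flagged(self):
        cells = self._cells({"a|A": (["DP", "DP", "CD8", "CD8", "CD8", "CD8", "CD8"],
                                     ["TUMOR"] * 7)})
        out = dp_clonotype_analysis(clonotype_table(cells))
        assert len(out) == 1 and not bool(out["dp_only"].iloc[0])
        assert out["n_dp"].iloc[0] == 2 and out["n_single_positive"].iloc[0] == 5

    def test_dp_only_clonotype_flagged(self):
        cells = self._cells({"a|A": (["DP", "DP"], ["TUMOR"] * 2)})
        out = dp_clonotype_analysis(clonotype_table(cells))
        assert bool(out["dp_only"].iloc[0])

    def test_planted_pattern_counts_recovered_exactly(self):
        # 56 DP-containing clonotypes: 26 TUMOR, 20 ALL, 10 TN
        spec = {}
        patterns = ["TUMOR"] * 26 + ["ALL"] * 20 + ["TN"] * 10
        for i, pat in enumerate(patterns):
            tissues = {"TUMOR": ["TUMOR"] * 3,
                       "ALL": ["TUMOR", "NAT", "PBMC"],
                       "TN": ["TUMOR", "NAT", "TUMOR"]}[pat]
            spec[f"dp{i}|K"] = (["DP", "CD8", "CD8"], tissues)
        for i in range(40):  # clonotypes without DP cells
            spec[f"sp{i}|K"] = (["CD8", "CD8"], ["TUMOR", "TUMOR"])
        out = dp_clonotype_analysis(clonotype_table(self._cells(spec)))
        counts = out["pattern"].value_counts()
        assert len(out) == 56
        assert counts["TUMOR"] == 26 and counts["ALL"] == 20 and counts["TN"] == 10
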