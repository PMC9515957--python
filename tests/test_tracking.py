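"""Tissue-pattern classification and cross-tissue clonotype tracking."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tilseq.tracking import (alluvial_table, classify_tissue_pattern,
                             flag_expanded, longitudinal_persistence,
                             pattern_summary, track_clonotypes)

from conftest import make_repertoire

ALL_SUBSETS = {
    frozenset({"TUMOR"}): "TUMOR",
    frozenset({"NAT"}): "NAT",
    frozenset({"PBMC"}): "PBMC",
    frozenset({"TUMOR", "NAT"}): "TN",
    frozenset({"TUMOR", "PBMC"}): "TP",
    frozenset({"NAT", "PBMC"}): "PN",
    frozenset({"TUMOR", "NAT", "PBMC"}): "ALL",
}


class TestPatternClassification:
    @pytest.mark.parametrize("subset,label", sorted(ALL_SUBSETS.items(),
                                                    key=lambda kv: kv[1]))
    def test_all_seven_nonempty_subsets(self, subset, label):
        assert classify_tissue_pattern(subset) == label

    def test_unknown_tissue_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="unknown tissue"):
            classify_tissue_pattern({"TUMOR", "SPLEEN"})

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            classify_tissue_pattern(set())


class TestExpansionFlag:
    @pytest.mark.parametrize("freq,expected", [
        (0.046, True),   # lower end of the dominant-clone range
        (0.24, True),    # upper end of the dominant-clone range
        (0.01, False),   # strict threshold: exactly 1% is not expanded
        (0.0101, True),
    ])
    def test_strict_one_percent_threshold(self, freq, expected):
        assert flag_expanded(freq) is expected

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ValueError):
            flag_expanded(1.5)


def _patient_reps(tumor=None, nat=None, pbmc=None):
    reps = []
    for tissue, freqs in (("TUMOR", tumor), ("NAT", nat), ("PBMC", pbmc)):
        if freqs is not None:
            reps.append(make_repertoire(freqs, sample_id=f"S_{tissue}",
                                        patient_id="P1", tissue=tissue))
    return reps


class TestTracking:
    def test_tumor_restricted_expanded_clone(self):
        reps = _patient_reps(tumor={"CASSA": 0.03, "CASSB": 0.97},
                             nat={"CASSC": 1.0}, pbmc={"CASSC": 1.0})
        tracked = track_clonotypes(reps).set_index("cdr3_aa")
        assert tracked.loc["CASSA", "pattern"] == "TUMOR"
        assert bool(tracked.loc["CASSA", "expanded_in_tumor"])

    def test_nat_pbmc_clone_is_pn_and_not_expanded(self):
        reps = _patient_reps(tumor={"CASSB": 1.0},
                             nat={"CASSA": 0.5, "CASSD": 0.5},
                             pbmc={"CASSA": 1.0})
        tracked = track_clonotypes(reps).set_index("cdr3_aa")
        assert tracked.loc["CASSA", "pattern"] == "PN"
        assert not bool(tracked.loc["CASSA", "expanded_in_tumor"])

    def test_pattern_counts_partition_unique_keys(self):
        reps = _patient_reps(tumor={"CASSA": 0.5, "CASSB": 0.5},
                             nat={"CASSB": 0.6, "CASSC": 0.4},
                             pbmc={"CASSB": 0.3, "CASSC": 0.3, "CASSD": 0.4})
        tracked = track_clonotypes(reps)
        assert pattern_summary(tracked).sum() == tracked["cdr3_aa"].nunique() == 4

    def test_classification_invariant_to_sample_order(self):
        reps = _patient_reps(tumor={"CASSA": 0.7, "CASSB": 0.3},
                             nat={"CASSA": 1.0}, pbmc={"CASSB": 1.0})
        frames = []
        for perm in itertools.permutations(reps):
            frames.append(track_clonotypes(list(perm)).set_index("cdr3_aa"))
        for other in frames[1:]:
            pd.testing.assert_frame_equal(frames[0], other)

    def test_duplicate_tissue_sample_is_ambiguity_error(self):
        reps = _patient_reps(tumor={"CASSA": 1.0})
        reps.append(make_repertoire({"CASSB": 1.0}, sample_id="S2",
                                    patient_id="P1", tissue="TUMOR"))
        with pytest.raises(ValueError, match="duplicate"):
            track_clonotypes(reps)

    def test_missing_tissue_never_claims_all(self):
        reps = _patient_reps(tumor={"CASSA": 1.0}, nat={"CASSA": 1.0})
        tracked = track_clonotypes(reps)
        assert tracked["pattern"].iloc[0] == "TN"
        assert tracked["tissues_assayed"].iloc[0] == "TUMOR,NAT"

    def test_downsampling_only_loses_shared_tissues(self):
        # removing reads from one tissue can only move a clone toward
        # fewer-tissue patterns, never add a tissue
        rng = np.random.default_rng(0)
        full = {f"CASS{c}": f for c, f in
                zip("ABCDEFGH", rng.dirichlet(np.ones(8)))}
        reps_full = _patient_reps(tumor=full, nat=full, pbmc=full)
        sub = dict(list(full.items())[:3])
        reps_sub = _patient_reps(tumor=full, nat=sub, pbmc=sub)
        t_full = track_clonotypes(reps_full).set_index("cdr3_aa")
        t_sub = track_clonotypes(reps_sub).set_index("cdr3_aa")
        tissues = lambda row: {t for t in ("TUMOR", "NAT", "PBMC")
                               if row[f"count_{t}"] > 0}
        for aa in t_sub.index:
            assert tissues(t_sub.loc[aa]) <= tissues(t_full.loc[aa])


class TestAlluvial:
    def test_all_clones_by_all_tissues_when_under_n(self):
        rng = np.random.default_rng(1)
        freqs = {f"CASS{i:03d}": f for i, f in
                 enumerate(rng.dirichlet(np.ones(50)))}
        reps = _patient_reps(tumor=freqs, nat=freqs, pbmc=freqs)
        table = alluvial_table(reps, n=120)
        assert len(table) == 50 * 3

    def test_tumor_restricted_clones_show_explicit_zeros(self):
        # three tumor-restricted dominant clones, absent from NAT and PBMC
        reps = _patient_reps(
            tumor={"CASSLRGTNYGYTF": 0.35, "CASGLTGSVEQFF": 0.15,
                   "CASSWGAEAFF": 0.10, "CASSX": 0.40},
            nat={"CASSY": 1.0}, pbmc={"CASSY": 1.0})
        table = alluvial_table(reps, n=120)
        for aa in ("CASSLRGTNYGYTF", "CASGLTGSVEQFF", "CASSWGAEAFF"):
            rows = table[table["cdr3_aa"] == aa].set_index("tissue")["frequency"]
            assert rows["NAT"] == 0.0 and rows["PBMC"] == 0.0 and rows["TUMOR"] > 0

    def test_n_equals_one_keeps_only_per_tissue_top_clones(self):
        reps = _patient_reps(tumor={"CASSA": 0.9, "CASSB": 0.1},
                             nat={"CASSB": 0.9, "CASSA": 0.1},
                             pbmc={"CASSA": 0.9, "CASSB": 0.1})
        table = alluvial_table(reps, n=1)
        assert set(table["cdr3_aa"]) == {"CASSA", "CASSB"}


class TestLongitudinal:
    def test_persistent_clone_tracked_to_later_timepoint(self):
        r0 = make_repertoire({"CASSA": 0.03, "CASSB": 0.97}, sample_id="t0",
                             tissue="PBMC", timepoint="yr0")
        r1 = make_repertoire({"CASSA": 0.038, "CASSB": 0.962}, sample_id="t1",
                             tissue="PBMC", timepoint="yr1")
        out = longitudinal_persistence([r0, r1]).set_index("cdr3_aa")
        assert bool(out.loc["CASSA", "persistent"])
        assert out.loc["CASSA", "max_frequency"] == pytest.approx(0.038, rel=1e-2)

    def test_vanished_clone_not_persistent(self):
        r0 = make_repertoire({"CASSA": 0.02, "CASSB": 0.98}, timepoint="yr0")
        r1 = make_repertoire({"CASSB": 1.0}, timepoint="yr1")
        out = longitudinal_persistence([r0, r1]).set_index("cdr3_aa")
        assert not bool(out.loc["CASSA", "persistent"])

    def test_single_timepoint_warns_and_returns_empty(self):
        r0 = make_repertoire({"CASSA": 1.0}, timepoint="yr0")
        with pytest.warns(UserWarning):
            out = longitudinal_persistence([r0])
        assert out.empty

    def test_stable_frequencies_recovered_within_sampling_error(self):
        rng = np.random.default_rng(2)
        p = np.array([0.3, 0.2, 0.5])
        reps = []
        for tp in ("yr0", "yr1"):
            counts = rng.multinomial(100_000, p)
            reps.append(make_repertoire(
                {f"CASS{c}": n / counts.sum() for c, n in zip("ABC", counts)},
                timepoint=tp, total_reads=100_000))
        out = longitudinal_persistence(reps).set_index("cdr3_aa")
        for aa, true_p in zip(["CASSA", "CASSB", "CASSC"], p):
            for col in ("freq_yr0", "freq_yr1"):
                assert out.loc[aa, col] == pytest.approx(true_p, abs=0.01)
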