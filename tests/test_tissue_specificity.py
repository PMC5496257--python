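"""Expressed sets, unique presence/absence, variable selection, bi-clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from equilnc.io_model import ExpressionMatrix
from equilnc.tissue_specificity import (bicluster, expressed_set,
                                        select_variable, tissue_report,
                                        uniquely_absent, uniquely_present)

from oracles import naive_average_linkage


def _expr(rows, tissues=None):
    tissues = tissues or [f"T{i}" for i in range(len(next(iter(rows.values()))))]
    return ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index",
                                                   columns=tissues).astype(float))


class TestExpressedSet:
    def test_threshold_is_strict(self):
        expr = _expr({"t1": [0.1], "t2": [0.11]})
        assert expressed_set(expr, "T0") == {"t2"}

    def test_unknown_tissue_rejected(self):
        with pytest.raises(KeyError):
            expressed_set(_expr({"t1": [1.0]}), "nope")

    def test_all_zero_matrix(self):
        assert expressed_set(_expr({"t1": [0.0, 0.0]}), "T0") == set()


class TestUniquePresence:
    def test_single_tissue_dominance(self):
        up = uniquely_present(_expr({"t1": [0.5, 0.01, 0.02]}))
        assert up == {"T0": {"t1"}, "T1": set(), "T2": set()}

    def test_two_expressed_tissues_not_unique(self):
        up = uniquely_present(_expr({"t1": [0.5, 0.5, 0.0]}))
        assert all(not s for s in up.values())

    def test_inclusive_boundary_at_0_1(self):
        up = uniquely_present(_expr({"t1": [0.1, 0.09, 0.09]}))
        assert up["T0"] == {"t1"}

    def test_assignments_disjoint_across_tissues(self):
        rng = np.random.default_rng(31)
        expr = _expr({f"t{i}": list(rng.lognormal(-2, 2, size=4))
                      for i in range(100)})
        up = uniquely_present(expr)
        tissues = list(up)
        for i, a in enumerate(tissues):
            for b in tissues[i + 1:]:
                assert not up[a] & up[b]


class TestUniqueAbsence:
    def test_single_tissue_silence(self):
        ua = uniquely_absent(_expr({"t1": [0.01, 0.5, 0.5]}))
        assert ua["T0"] == {"t1"} and not ua["T1"] and not ua["T2"]

    def test_others_must_be_strictly_above(self):
        ua = uniquely_absent(_expr({"t1": [0.01, 0.5, 0.1]}))
        assert all(not s for s in ua.values())

    def test_two_tissue_transcript_both_classifications(self):
        expr = _expr({"t1": [0.01, 5.0]})
        assert uniquely_absent(expr)["T0"] == {"t1"}
        assert uniquely_present(expr)["T1"] == {"t1"}


class TestSelectVariable:
    def test_high_sum_high_sd_selected(self):
        # sd of (200, 0) = 141.4 with n-1 denominator
        assert select_variable(_expr({"t1": [200.0, 0.0]})) == {"t1"}

    def test_high_sum_zero_sd_not_selected(self):
        assert select_variable(_expr({"t1": [60.0, 60.0]})) == set()

    def test_low_sum_not_selected(self):
        assert select_variable(_expr({"t1": [30.0, 30.0]})) == set()

    def test_sample_standard_deviation_used(self):
        # sd_1(80, 21) ~ 41.7 < 50 but population sd ~ 29.5; sum 101 > 100
        assert select_variable(_expr({"t1": [80.0, 21.0]}), sd_min=41.0) == {"t1"}
        assert select_variable(_expr({"t1": [80.0, 21.0]}), sd_min=42.0) == set()


class TestBicluster:
    def test_identical_rows_merge_first(self):
        rng = np.random.default_rng(37)
        base = rng.random(5) * 10
        rows = {"a": list(base), "b": list(base), "c": list(rng.random(5) * 10),
                "d": list(rng.random(5) * 10)}
        _, _, row_link, _ = bicluster(_expr(rows))
        assert set(row_link[0, :2]) == {0.0, 1.0}
        assert row_link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_identical_rank_profiles_have_zero_spearman_distance(self):
        rows = {"a": [1.0, 5.0, 2.0], "b": [2.0, 50.0, 30.0],
                "c": [10.0, 1.0, 0.5]}
        _, tissue_order, _, col_link = bicluster(_expr(rows))
        # tissues T1 and T2 rank transcripts identically
        assert col_link[0, 2] == pytest.approx(0.0, abs=1e-12)
        i, j = int(col_link[0, 0]), int(col_link[0, 1])
        assert {i, j} == {1, 2}

    def test_zero_variance_row_warns(self):
        rows = {"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0], "c": [3.0, 1.0, 2.0]}
        with pytest.warns(UserWarning, match="zero-variance"):
            bicluster(_expr(rows))

    def test_tissue_clustering_matches_reference_implementation(self):
        """Exact match of merges, heights and leaf order vs naive UPGMA."""
        rng = np.random.default_rng(41)
        for trial in range(20):
            mat = rng.lognormal(0, 1, size=(20, 5))
            df = pd.DataFrame(mat, index=[f"t{i}" for i in range(20)],
                              columns=[f"s{j}" for j in range(5)])
            _, tissue_order, _, col_link = bicluster(ExpressionMatrix(df))
            # oracle: full 1 - spearman distance matrix, naive agglomeration
            dist = np.zeros((5, 5))
            for i in range(5):
                for j in range(i + 1, 5):
                    rho = spearmanr(mat[:, i], mat[:, j]).statistic
                    dist[i, j] = dist[j, i] = 1.0 - rho
            merges, leaf_order = naive_average_linkage(dist)
            ours_merges = []
            members = {i: frozenset([i]) for i in range(5)}
            for k, (a, b, h, _) in enumerate(col_link):
                members[5 + k] = members[int(a)] | members[int(b)]
                ours_merges.append((members[5 + k], h))
            for (set_a, h_a), (set_b, h_b) in zip(ours_merges, merges):
                assert set_a == set_b, f"trial {trial}"
                assert h_a == pytest.approx(h_b, abs=1e-10)
            assert tissue_order == [f"s{j}" for j in leaf_order], f"trial {trial}"

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            bicluster(pd.DataFrame())


class TestTissueReport:
    def _report(self, rows):
        expr = _expr(rows, tissues=["A", "B", "C"])
        lnc = {t for t in rows if t.startswith("l")}
        coding = {t for t in rows if t.startswith("c")}
        return tissue_report(expr, lnc, coding)

    def test_counts_and_ratio(self):
        rep = self._report({"l1": [1.0, 0.0, 1.0], "l2": [1.0, 1.0, 0.0],
                            "c1": [1.0, 1.0, 1.0], "c2": [1.0, 0.0, 0.0]})
        row = rep.table.loc["A"]
        assert row["n_expressed_lnc"] == 2 and row["n_expressed_coding"] == 2
        assert row["ratio"] == pytest.approx(1.0)
        assert rep.table.loc["B", "ratio"] == pytest.approx(1.0)

    def test_cumulative_tpm_sums_expressed_only(self):
        rep = self._report({"l1": [2.0, 0.05, 0.0], "c1": [3.0, 1.0, 0.0]})
        assert rep.table.loc["A", "cumulative_tpm_lnc"] == pytest.approx(2.0)
        assert rep.table.loc["B", "cumulative_tpm_lnc"] == 0.0

    def test_permutation_invariance(self):
        rows = {"l1": [1.0, 0.0, 2.0], "l2": [0.0, 3.0, 1.0],
                "c1": [2.0, 2.0, 2.0]}
        a = self._report(rows).table
        b = self._report(dict(reversed(list(rows.items())))).table
        pd.testing.assert_frame_equal(a, b)


class TestPlantedRecovery:
    def test_uniquely_present_recovers_planted_assignments(self, default_dataset):
        """Noise-free regime: planted tissue-specific lncRNA, and only
        those, are classified uniquely present, each in its own tissue."""
        ds = default_dataset
        truth = ds.truth
        lnc_ids = set(truth.index[truth["class"] == "true_lncRNA"])
        up = uniquely_present(ds.expr.subset(sorted(lnc_ids)))
        planted = truth[truth["planted_tissue"] != ""]
        for tissue, _prep in ds.config.tissues:
            want = set(planted.index[planted["planted_tissue"] == tissue]) & lnc_ids
            assert up[tissue] == want

    def test_polya_capture_detects_fewer_lncrna(self, default_dataset):
        """polyA-captured tissues see fewer expressed lncRNA than
        rRNA-depleted tissues (library-prep detection bias)."""
        ds = default_dataset
        lnc_ids = set(ds.truth.index[ds.truth["class"] == "true_lncRNA"])
        expr = ds.expr.subset(sorted(lnc_ids))
        counts = {prep: [] for _, prep in ds.config.tissues}
        for tissue, prep in ds.config.tissues:
            counts[prep].append(len(expressed_set(expr, tissue)))
        assert max(counts["polyA"]) < min(counts["rRNA_depleted"])
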