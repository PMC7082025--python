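"""Preprocessing and differential-expression unit tests."""

import numpy as np
import pandas as pd
import pytest

from anhydronet import prep


def bh_step_up_oracle(p):
    """Literal step-up definition: adj_(i) = min_{j>=i} min(1, m p_(j)/j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(min(1.0, m * p[order[j]] / (j + 1))
                            for j in range(i, m))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestRpkm:
    def test_hand_value(self):
        counts = prep.CountMatrix(
            pd.DataFrame({"s": [10, 999_990]}, index=["g", "filler"]),
            pd.Series([1000.0, 1000.0], index=["g", "filler"]))
        rpkm = prep.rpkm_transform(counts)
        # 1e9 * 10 / (1e3 * 1e6) = 10
        assert rpkm.loc["g", "s"] == pytest.approx(10.0)

    def test_zero_count_maps_to_zero(self, small_counts):
        counts, _ = small_counts
        counts.values.iloc[0, 0] = 0
        assert prep.rpkm_transform(counts).iloc[0, 0] == 0.0

    def test_joint_scaling_invariance(self, small_counts):
        counts, _ = small_counts
        doubled = prep.CountMatrix(counts.values * 2, counts.gene_length_bp)
        np.testing.assert_allclose(prep.rpkm_transform(doubled).to_numpy(),
                                   prep.rpkm_transform(counts).to_numpy())

    def test_zero_library_rejected(self, small_counts):
        counts, _ = small_counts
        counts.values.iloc[:, 0] = 0
        with pytest.raises(ValueError, match="library"):
            prep.rpkm_transform(counts)


class TestPca:
    def test_duplicate_samples_coincide(self, rng):
        x = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        x["e"] = x["a"]
        res = prep.principal_components(x, 3)
        np.testing.assert_allclose(res.scores.loc["a"], res.scores.loc["e"],
                                   atol=1e-10)

    def test_ratios_nonincreasing_and_bounded(self, rng):
        x = pd.DataFrame(rng.normal(size=(30, 6)))
        res = prep.principal_components(x, 3)
        assert np.all(np.diff(res.contribution_ratio) <= 1e-12)
        assert res.contribution_ratio.sum() <= 1 + 1e-9

    def test_rank_one_matrix(self, rng):
        base = rng.normal(size=20)
        x = pd.DataFrame(np.outer(base, [1.0, 2.0, -1.0, 0.5]))
        res = prep.principal_components(x, 2)
        assert res.contribution_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_constant_matrix_warns(self):
        x = pd.DataFrame(np.ones((5, 4)))
        with pytest.warns(UserWarning):
            res = prep.principal_components(x, 2)
        assert np.all(res.scores.to_numpy() == 0)


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(prep.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_singleton_identity(self):
        assert prep.bh_adjust([0.5]) == pytest.approx([0.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(prep.bh_adjust(p), bh_step_up_oracle(p),
                                   atol=1e-12)

    def test_dominates_input(self, rng):
        p = rng.random(100)
        adj = prep.bh_adjust(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            prep.bh_adjust([0.5, 1.2])


class TestNbLrt:
    def test_identical_counts_not_deg(self, small_counts):
        counts, design = small_counts
        counts.values.loc["g1"] = 100
        res = prep.nb_lrt(counts, design, "trehalose")
        assert res.table.loc["g1", "lrt_statistic"] == pytest.approx(0.0, abs=0.5)
        assert res.table.loc["g1", "p_value"] > 0.5
        assert not res.table.loc["g1", "is_deg"]

    def test_all_zero_gene_flagged(self, small_counts):
        counts, design = small_counts
        counts.values.loc["g2"] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            res = prep.nb_lrt(counts, design, "trehalose")
        assert res.table.loc["g2", "p_value"] == 1.0
        assert not res.table.loc["g2", "tested"]

    def test_replicate_permutation_invariance(self, small_counts):
        counts, design = small_counts
        res1 = prep.nb_lrt(counts, design, "trehalose")
        # swap the two replicates of one time point
        swapped = counts.values.copy()
        swapped[["T1_1", "T1_2"]] = swapped[["T1_2", "T1_1"]].to_numpy()
        res2 = prep.nb_lrt(prep.CountMatrix(swapped, counts.gene_length_bp),
                           design, "trehalose")
        np.testing.assert_allclose(res1.table["lrt_statistic"],
                                   res2.table["lrt_statistic"], rtol=1e-8)

    def test_statistic_matches_statsmodels_glm(self, small_counts):
        """The vectorized NB fits agree with statsmodels GLM at the same
        fixed dispersion (independent oracle for the likelihood ratio)."""
        import statsmodels.api as sm

        counts, design = small_counts
        res = prep.nb_lrt(counts, design, "trehalose")
        samples = design.samples_for("trehalose")
        sub = design.table.loc[samples]
        totals = counts.values[samples].sum(axis=0).to_numpy(float)
        exposure = totals / totals.mean()
        times = pd.get_dummies(sub["time_h"]).to_numpy(float)
        for gene in counts.gene_ids[:3]:
            alpha = res.table.loc[gene, "dispersion"]
            y = counts.values.loc[gene, samples].to_numpy(float)
            fam = sm.families.NegativeBinomial(alpha=alpha)
            full = sm.GLM(y, times, family=fam, exposure=exposure).fit()
            red = sm.GLM(y, np.ones((len(y), 1)), family=fam,
                         exposure=exposure).fit()
            oracle_stat = 2.0 * (full.llf - red.llf)
            assert res.table.loc[gene, "lrt_statistic"] == pytest.approx(
                oracle_stat, abs=1e-4)

    def test_strong_shift_detected(self, small_counts):
        counts, design = small_counts
        counts.values.loc["g3", ["T2_1", "T2_2"]] = 2000
        res = prep.nb_lrt(counts, design, "trehalose")
        assert res.table.loc["g3", "is_deg"]


class TestPartition:
    def _deg_table(self, genes, degs, condition):
        table = pd.DataFrame(index=genes)
        table["is_deg"] = [g in degs for g in genes]
        for col, val in (("lrt_statistic", 1.0), ("df", 2), ("p_value", 0.5),
                         ("fdr", 0.5), ("tested", True)):
            table[col] = val
        return prep.DegTable(table, condition)

    def test_four_way_counts(self):
        genes = [f"g{i}" for i in range(6)]
        go = {"g0": {prep.TF_GO_TERM}, "g1": {prep.TF_GO_TERM}, "g2": set()}
        deg = {"trehalose": self._deg_table(genes, {"g0", "g1", "g2"}, "trehalose"),
               "rehydration": self._deg_table(genes, {"g1", "g3"}, "rehydration")}
        venn = prep.partition_tf_targets(deg, go)
        assert venn.tf == {"trehalose_only": 1, "rehydration_only": 0, "both": 1}
        assert venn.other == {"trehalose_only": 1, "rehydration_only": 1, "both": 0}

    def test_empty_deg_sets(self):
        genes = ["a", "b"]
        deg = {"trehalose": self._deg_table(genes, set(), "trehalose"),
               "rehydration": self._deg_table(genes, set(), "rehydration")}
        venn = prep.partition_tf_targets(deg, {})
        assert sum(venn.tf.values()) == 0 and sum(venn.other.values()) == 0
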