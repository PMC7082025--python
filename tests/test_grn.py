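"""Network inference, scale-free thresholding and signing unit tests."""

import numpy as np
import pandas as pd
import pytest

from anhydronet import grn


class TestScoreRegulators:
    def test_lagged_copy_regulator_wins(self):
        rng = np.random.default_rng(3)
        t = 200
        a = rng.normal(size=t)
        target = np.concatenate([[0.0], a[:-1]])
        noise = rng.normal(size=(3, t))
        series = np.stack([a, target, *noise])[:, :, None]
        ids = ["A", "target", "n1", "n2", "n3"]
        scores = grn.score_regulators(series, ids, "c", seed=0)
        col = scores.values["target"]
        assert col.idxmax() == "A"
        assert col["A"] > 0.8

    def test_constant_target_zero_row(self, rng):
        series = rng.normal(size=(3, 30))
        series[1] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            scores = grn.score_regulators(series[:, :, None], list("ABC"), "c",
                                          seed=0)
        assert scores.values["B"].fillna(0).sum() == 0.0

    def test_per_target_sums_zero_or_one(self, rng):
        series = rng.normal(size=(5, 25, 2))
        scores = grn.score_regulators(series, list("ABCDE"), "c", seed=1)
        sums = scores.values.sum(axis=0, skipna=True)
        assert np.all((np.abs(sums - 1) < 1e-9) | (np.abs(sums) < 1e-12))

    def test_permutation_equivariance(self, rng):
        series = rng.normal(size=(4, 40))
        ids = list("ABCD")
        s1 = grn.score_regulators(series[:, :, None], ids, "c", seed=9)
        perm = [2, 0, 3, 1]
        s2 = grn.score_regulators(series[perm][:, :, None],
                                  [ids[i] for i in perm], "c", seed=9)
        v1 = s1.values.loc[ids, ids].to_numpy()
        v2 = s2.values.loc[ids, ids].to_numpy()
        np.testing.assert_allclose(np.nan_to_num(v1), np.nan_to_num(v2))

    def test_too_short_series_rejected(self, rng):
        with pytest.raises(ValueError):
            grn.score_regulators(rng.normal(size=(3, 2)), list("ABC"), "c")


class TestScaleFreeFit:
    def test_exact_geometric_construction(self):
        degrees = [1] * 8 + [2] * 4 + [4] * 2 + [8]
        fit = grn.fit_scale_free(degrees)
        assert fit.gamma == pytest.approx(1.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit.slope == pytest.approx(-1.0, abs=1e-10)

    def test_single_degree_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            fit = grn.fit_scale_free([3, 3, 3, 3])
        assert not fit.defined

    def test_uniform_degrees_flat(self):
        degrees = [1] * 10 + [2] * 10 + [3] * 10 + [4] * 10
        fit = grn.fit_scale_free(degrees)
        assert abs(fit.gamma) < 1e-9
        assert not (fit.f_test_p < 0.05)


def planted_cutoff_scores(seed, n=200, cutoff=0.5):
    """Preferential-attachment signal above the cutoff; dense uniform noise
    in a band just below it, so one threshold step under the cutoff floods
    the graph. Returns the matrix and the cutoff on the normalized scale."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.barabasi_albert_graph(n, 3, seed=int(seed))
    mat = np.round(rng.uniform(cutoff - 0.03, cutoff - 0.01, size=(n, n)), 2)
    edges = list(g.edges())
    for u, v in edges:
        if rng.random() < 0.5:
            u, v = v, u
        mat[u, v] = np.round(rng.uniform(cutoff, 1.0), 2)
    # anchor the score range so min-max normalization is the identity
    mat[edges[0][0], edges[0][1]] = 1.0
    mat[1, 0] = 0.0
    np.fill_diagonal(mat, np.nan)
    ids = [f"T{i}" for i in range(n)]
    return grn.ScoreMatrix(pd.DataFrame(mat, index=ids, columns=ids), "c"), cutoff


class TestSelectThreshold:
    def test_all_equal_scores_error(self):
        mat = np.full((4, 4), 0.3)
        np.fill_diagonal(mat, np.nan)
        scores = grn.ScoreMatrix(pd.DataFrame(mat, index=list("ABCD"),
                                              columns=list("ABCD")), "c")
        with pytest.raises(grn.ThresholdError):
            grn.select_threshold(scores)

    def test_edge_count_antitone(self):
        scores, _ = planted_cutoff_scores(0, n=60)
        scan = grn.select_threshold(scores)
        assert np.all(np.diff(scan.table["n_edges"]) <= 0)

    def test_recovers_planted_cutoff_single_seed(self):
        scores, cut_norm = planted_cutoff_scores(1)
        scan = grn.select_threshold(scores)
        assert abs(scan.selected_a - cut_norm) <= 0.015  # one 0.01 step + rounding

    def test_selected_satisfies_rule(self):
        scores, _ = planted_cutoff_scores(2)
        scan = grn.select_threshold(scores)
        row = scan.table[np.isclose(scan.table["a"], scan.selected_a)].iloc[0]
        assert row["slope"] < 0 and row["f_test_p"] < 0.05


class TestAssignSigns:
    def test_shifted_copy_positive(self):
        a = np.sin(np.linspace(0, 6, 30))
        b = np.concatenate([[0], a[:-1]])
        net = grn.assign_signs([("A", "B", 0.9)], np.stack([a, b]), ["A", "B"],
                               "treh")
        assert net.edges[("A", "B")].sign == 1
        assert net.edges[("A", "B")].lag1_crosscorr > 0.9

    def test_negated_shift_negative(self):
        a = np.sin(np.linspace(0, 6, 30))
        b = -np.concatenate([[0], a[:-1]])
        net = grn.assign_signs([("A", "B", 0.9)], np.stack([a, b]), ["A", "B"],
                               "treh")
        assert net.edges[("A", "B")].sign == -1

    def test_constant_series_drops_edge(self):
        a = np.ones(20)
        b = np.arange(20.0)
        with pytest.warns(UserWarning, match="dropped"):
            net = grn.assign_signs([("A", "B", 0.5)], np.stack([a, b]),
                                   ["A", "B"], "treh")
        assert ("A", "B") not in net.edges


class TestIntegrate:
    def _net(self, items, condition):
        net = grn.SignedNetwork()
        for (u, v, sign, cc) in items:
            net.edges[(u, v)] = grn.Edge(sign, 0.5, (condition,), cc)
        return net

    def test_disjoint_union(self):
        a = self._net([("X", "Y", 1, 0.9)], "trehalose")
        b = self._net([("Y", "Z", -1, -0.8)], "rehydration")
        merged = grn.integrate_networks(a, b)
        assert set(merged.edges) == {("X", "Y"), ("Y", "Z")}
        assert merged.edges[("X", "Y")].conditions == ("trehalose",)

    def test_shared_edge_same_sign(self):
        a = self._net([("X", "Y", 1, 0.9)], "trehalose")
        b = self._net([("X", "Y", 1, 0.7)], "rehydration")
        merged = grn.integrate_networks(a, b)
        e = merged.edges[("X", "Y")]
        assert e.conditions == ("trehalose", "rehydration")
        assert not e.sign_conflict

    def test_sign_conflict_resolved_by_crosscorr(self):
        a = self._net([("X", "Y", 1, 0.4)], "trehalose")
        b = self._net([("X", "Y", -1, -0.8)], "rehydration")
        merged = grn.integrate_networks(a, b)
        e = merged.edges[("X", "Y")]
        assert e.sign == -1 and e.sign_conflict


def test_signed_network_tsv_round_trip(tmp_path):
    net = grn.SignedNetwork({("A", "B"): grn.Edge(1, 0.7, ("trehalose",), 0.9),
                             ("B", "C"): grn.Edge(-1, 0.4, ("trehalose",
                                                            "rehydration"), -0.5,
                                                  sign_conflict=True)})
    path = tmp_path / "net.tsv"
    net.write_tsv(path)
    loaded = grn.SignedNetwork.read_tsv(path)
    assert loaded.edges.keys() == net.edges.keys()
    assert loaded.edges[("B", "C")].sign == -1
    assert loaded.edges[("B", "C")].sign_conflict
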