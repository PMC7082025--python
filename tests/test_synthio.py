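"""Synthetic-data generator unit tests."""

import numpy as np
import pytest

from anhydronet import synthio
from anhydronet.regcall import Pwm


class TestGeneratePlantedNetwork:
    def test_minimal_coherent_ffl_all_positive(self):
        net = synthio.generate_planted_network(3, 0, 1.0, ["coherent_ffl"], seed=1)
        got = {(u, v): s for u, v, s, _w in net.edges}
        a, b, c = net.planted_motifs[0][1]
        assert got == {(a, b): 1, (b, c): 1, (a, c): 1}

    def test_positive_fbl_even_negatives(self):
        net = synthio.generate_planted_network(3, 0, 1.0, ["positive_fbl"], seed=1)
        signs = [s for _u, _v, s, _w in net.edges]
        assert len(signs) == 3
        assert sum(s < 0 for s in signs) % 2 == 0

    def test_determinism(self):
        a = synthio.generate_planted_network(12, 20, 0.6, ["incoherent_ffl"], seed=7)
        b = synthio.generate_planted_network(12, 20, 0.6, ["incoherent_ffl"], seed=7)
        assert a.edges == b.edges
        assert a.planted_motifs == b.planted_motifs

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            synthio.generate_planted_network(4, 100, 0.5, [], seed=0)

    def test_master_has_zero_in_degree(self):
        net = synthio.generate_planted_network(
            15, 20, 0.7, ["coherent_ffl", "positive_fbl"], seed=3, master=True)
        assert net.master_regulator == net.tf_ids[0]
        assert not any(v == net.master_regulator for _u, v, _s, _w in net.edges)

    def test_connect_gives_every_tf_a_regulator(self):
        net = synthio.generate_planted_network(
            20, 5, 0.7, ["coherent_ffl"], seed=3, master=True, connect=True,
            protect_motifs=True)
        targets = {v for _u, v, _s, _w in net.edges}
        for tf in net.tf_ids:
            if tf != net.master_regulator:
                assert tf in targets

    def test_motif_signs_validated(self):
        with pytest.raises(ValueError, match="signs inconsistent"):
            synthio.PlantedNetwork(
                ["A", "B", "C"],
                [("A", "B", 1, 1.0), ("B", "C", 1, 1.0), ("A", "C", -1, 1.0)],
                [("coherent_ffl", ("A", "B", "C"))])

    def test_duplicate_edges_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            synthio.PlantedNetwork(["A", "B"],
                                   [("A", "B", 1, 1.0), ("A", "B", -1, 0.5)])


class TestDynamics:
    def test_noise_free_shift(self, chain_network):
        cfg = synthio.SimulationConfig(n_timepoints=8, noise_sd=0.0, seed=0)
        rng = np.random.default_rng(0)
        x = synthio.simulate_latent_tfs(chain_network, cfg, rng)
        a, b, c = x
        np.testing.assert_allclose(b[1:], 1.0 * a[:-1])
        np.testing.assert_allclose(c[1:], -0.8 * b[:-1])

    def test_linearity_doubling_root(self, chain_network):
        cfg = synthio.SimulationConfig(n_timepoints=10, noise_sd=0.0, seed=0)
        rng = np.random.default_rng(0)
        x0 = np.array([1.5, 0.3, -0.7])
        x1 = synthio.simulate_latent_tfs(chain_network, cfg, rng, x0=x0)
        x2 = synthio.simulate_latent_tfs(chain_network, cfg, rng, x0=2 * x0)
        np.testing.assert_allclose(x2, 2 * x1, atol=1e-12)

    def test_replicates_coincide_without_noise(self, chain_network):
        truth = synthio.make_module_truth({"M1": ("A", 1)}, 5, 3)
        cfg = synthio.SimulationConfig(n_timepoints=5, n_replicates=2,
                                       noise_sd=0.0, nb_dispersion=0.0,
                                       library_size=10_000_000, seed=0)
        ds = synthio.simulate_expression(chain_network, truth, cfg)
        r1 = ds.counts.values[[s for s in ds.counts.sample_ids if s.endswith("_1")]]
        r2 = ds.counts.values[[s for s in ds.counts.sample_ids if s.endswith("_2")]]
        # identical latents; only Poisson noise differs at high depth
        ratio = (r1.to_numpy() + 1) / (r2.to_numpy() + 1)
        assert np.abs(np.log(ratio)).max() < 0.2


class TestCounts:
    def test_poisson_limit_variance(self, rng):
        mu = np.full(10_000, 50.0)
        draws = synthio._nb_draw(rng, mu, 0.0)
        assert abs(draws.var() / draws.mean() - 1.0) < 0.1

    def test_nb_variance_function(self, rng):
        mu_val, disp = 100.0, 0.1
        draws = synthio._nb_draw(rng, np.full(20_000, mu_val), disp)
        expected = mu_val + disp * mu_val**2
        assert draws.var() == pytest.approx(expected, rel=0.1)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            synthio.SimulationConfig(nb_dispersion=-0.1)

    def test_gene_conservation(self, chain_network):
        truth = synthio.make_module_truth({"M1": ("A", 1), "M2": ("B", -1)}, 4, 7)
        cfg = synthio.SimulationConfig(seed=1)
        ds = synthio.simulate_expression(chain_network, truth, cfg)
        assert len(ds.counts.gene_ids) == 3 + 8 + 7

    def test_determinism(self, chain_network):
        truth = synthio.make_module_truth({"M1": ("A", 1)}, 3, 2)
        cfg = synthio.SimulationConfig(seed=11)
        d1 = synthio.simulate_expression(chain_network, truth, cfg)
        d2 = synthio.simulate_expression(chain_network, truth, cfg)
        assert d1.counts.values.equals(d2.counts.values)

    def test_unknown_driver_rejected(self, chain_network):
        truth = synthio.make_module_truth({"M1": ("Z", 1)}, 3, 0)
        with pytest.raises(ValueError, match="driver"):
            synthio.simulate_expression(chain_network, truth,
                                        synthio.SimulationConfig())


def one_hot_pwm(motif_id, consensus):
    mat = np.full((len(consensus), 4), 0.0)
    for i, base in enumerate(consensus):
        mat[i, "ACGT".index(base)] = 1.0
    return Pwm(motif_id, mat)


class TestPromoters:
    def setup_method(self):
        self.truth = synthio.make_module_truth({"M1": ("A", 1)}, 20, 10)
        self.pwm = one_hot_pwm("mot1", "ACGTACGTTGCA")

    def test_certain_insertion_plants_consensus(self):
        seqs = synthio.generate_promoters(self.truth, [self.pwm],
                                          [("mot1", "M1", 1.0)], 300, 0.5, seed=0)
        comp = str.maketrans("ACGT", "TGCA")
        rc = self.pwm.consensus.translate(comp)[::-1]
        for g in self.truth.genes_in("M1"):
            assert self.pwm.consensus in seqs[g] or rc in seqs[g]

    def test_zero_insertion_probability(self):
        seqs = synthio.generate_promoters(self.truth, [self.pwm],
                                          [("mot1", "M1", 0.0)], 300, 0.5, seed=0)
        comp = str.maketrans("ACGT", "TGCA")
        rc = self.pwm.consensus.translate(comp)[::-1]
        hits = sum(self.pwm.consensus in seqs[g] or rc in seqs[g]
                   for g in self.truth.genes_in("M1"))
        assert hits == 0

    def test_gc_content(self):
        truth = synthio.make_module_truth({"M1": ("A", 1)}, 50, 50)
        seqs = synthio.generate_promoters(truth, [], [], 10_000, 0.5, seed=0)
        joined = "".join(seqs.values())
        gc = (joined.count("G") + joined.count("C")) / len(joined)
        se = np.sqrt(0.25 / len(joined))
        assert abs(gc - 0.5) < 3 * se

    def test_pwm_longer_than_upstream_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            synthio.generate_promoters(self.truth, [self.pwm],
                                       [("mot1", "M1", 1.0)], 8, 0.5, seed=0)

    def test_deterministic(self):
        a = synthio.generate_promoters(self.truth, [self.pwm],
                                       [("mot1", "M1", 0.5)], 200, 0.4, seed=5)
        b = synthio.generate_promoters(self.truth, [self.pwm],
                                       [("mot1", "M1", 0.5)], 200, 0.4, seed=5)
        assert a == b


def test_write_dataset_round_trip(tmp_path, chain_network):
    truth = synthio.make_module_truth({"M1": ("A", 1)}, 4, 3)
    cfg = synthio.SimulationConfig(seed=2)
    ds = synthio.simulate_expression(chain_network, truth, cfg)
    ds.go_annotation = synthio.make_go_annotation(chain_network, truth)
    ds.pwms = synthio.make_pwms(["SRC_A"], seed=0)
    ds.promoters = synthio.generate_promoters(truth, ds.pwms,
                                              [("SRC_A", "M1", 1.0)], 100, 0.5,
                                              seed=0)
    manifest = synthio.write_dataset(ds, tmp_path)
    assert "counts.tsv" in manifest and "promoters.fasta" in manifest

    from anhydronet import prep
    counts = prep.CountMatrix.read_tsv(tmp_path / "counts.tsv")
    assert counts.values.shape == ds.counts.values.shape
    seqs = synthio.read_promoters(tmp_path / "promoters.fasta")
    assert seqs == ds.promoters
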