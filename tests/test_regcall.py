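"""Motif-enrichment and Granger-causality unit tests."""

import numpy as np
import pytest

from anhydronet import regcall
from anhydronet.regcall import Pwm


def one_hot(consensus):
    mat = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = 1.0
    return Pwm("m", mat)


class TestScanPwm:
    def test_perfect_match_score(self):
        pwm = one_hot("ACGT")
        # each consensus position contributes log2(1/0.25) = 2 bits
        assert regcall.scan_pwm(pwm, "TTTACGTTT") == pytest.approx(8.0)

    def test_uniform_pwm_scores_zero(self):
        pwm = Pwm("u", np.full((5, 4), 0.25))
        assert regcall.scan_pwm(pwm, "ACGTACGTACGT") == pytest.approx(0.0)

    def test_strand_symmetry(self):
        pwm = one_hot("ACGGTT")
        seq = "GGGACGGTTCCCATG"
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        assert regcall.scan_pwm(pwm, seq) == pytest.approx(regcall.scan_pwm(pwm, rc))

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            regcall.scan_pwm(one_hot("ACGTAC"), "ACG")

    def test_ambiguity_codes_score_background(self):
        pwm = one_hot("ACGT")
        assert regcall.scan_pwm(pwm, "NNNNN") == pytest.approx(0.0)


class TestMotifEnrichment:
    def _random_seqs(self, rng, n, length=200):
        return {f"s{i}": "".join(rng.choice(list("ACGT"), size=length))
                for i in range(n)}

    def test_single_draw_granularity(self, rng):
        pwm = one_hot("ACGTAC")
        mod = self._random_seqs(rng, 3)
        bg = self._random_seqs(rng, 10)
        res = regcall.motif_enrichment(pwm, mod, bg, window_lengths=(100,),
                                       n_draws=1, seed=0, module="m")
        assert res.per_window["p_value"].iloc[0] in (0.5, 1.0)

    def test_planted_consensus_enriched(self, rng):
        pwm = one_hot("ACGTACGTTGCA")
        mod = {k: v[:90] + pwm.consensus + v[102:]
               for k, v in self._random_seqs(rng, 10).items()}
        bg = self._random_seqs(rng, 40)
        res = regcall.motif_enrichment(pwm, mod, bg, window_lengths=(200,),
                                       n_draws=300, seed=0, module="m")
        assert res.min_p < 0.05 and res.any_window_significant

    def test_null_module_not_enriched(self, rng):
        pwm = one_hot("ACGTACGTTGCA")
        mod = self._random_seqs(rng, 8)
        bg = self._random_seqs(rng, 40)
        res = regcall.motif_enrichment(pwm, mod, bg, window_lengths=(200,),
                                       n_draws=300, seed=1, module="m")
        assert res.min_p > 0.05

    def test_background_duplication_stability(self, rng):
        pwm = one_hot("ACGTAC")
        mod = self._random_seqs(rng, 5)
        bg = self._random_seqs(rng, 30)
        bg2 = dict(bg)
        bg2.update({k + "_dup": v for k, v in bg.items()})
        p1 = regcall.motif_enrichment(pwm, mod, bg, (150,), n_draws=500,
                                      seed=0, module="m").min_p
        p2 = regcall.motif_enrichment(pwm, mod, bg2, (150,), n_draws=500,
                                      seed=0, module="m").min_p
        assert abs(p1 - p2) < 0.12

    def test_empty_module_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            regcall.motif_enrichment(one_hot("ACGT"), {},
                                     self._random_seqs(rng, 5), (100,), 100, 0)


class TestGranger:
    def test_directional_detection(self):
        rng = np.random.default_rng(4)
        cause = rng.normal(size=100)
        effect = 0.9 * np.concatenate([[0], cause[:-1]]) + 0.1 * rng.normal(size=100)
        fwd = regcall.granger_causality(cause, effect, max_lag=2)
        rev = regcall.granger_causality(effect, cause, max_lag=2)
        assert fwd.p_value < 0.01
        assert rev.p_value > fwd.p_value

    def test_constant_series_flagged(self):
        res = regcall.granger_causality(np.ones(30), np.random.default_rng(0).normal(size=30))
        assert res.flagged and res.p_value == 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        cause = rng.normal(size=60)
        effect = 0.7 * np.concatenate([[0], cause[:-1]]) + 0.3 * rng.normal(size=60)
        base = regcall.granger_causality(cause, effect, max_lag=2)
        scaled = regcall.granger_causality(3.0 * cause - 1.0, 0.5 * effect + 2.0,
                                           max_lag=2)
        assert base.p_value == pytest.approx(scaled.p_value, rel=1e-6)

    def test_lag_capped_for_short_series(self):
        rng = np.random.default_rng(0)
        res = regcall.granger_causality(rng.normal(size=8), rng.normal(size=8),
                                        max_lag=5)
        assert res.selected_lag <= 2


class TestCalls:
    def _motif(self, tf, module, p):
        import pandas as pd
        return regcall.MotifHitResult(
            tf, module, pd.DataFrame({"window": [100], "statistic": [1.0],
                                      "p_value": [p]}), p < 0.05, p)

    def _granger(self, tf, module, p):
        return regcall.GrangerResult(tf, module, "trehalose", 1, 5.0, p)

    def test_joint_rule(self):
        motif = [self._motif("T1", "blue", 0.01), self._motif("T2", "blue", 0.01)]
        granger = regcall.adjust_granger(
            [self._granger("T1", "blue", 0.001), self._granger("T2", "blue", 0.9)])
        calls = {(c.tf_id, c.module): c.called
                 for c in regcall.call_regulators(motif, granger)}
        assert calls[("T1", "blue")] and not calls[("T2", "blue")]

    def test_called_set_is_intersection(self):
        rng = np.random.default_rng(0)
        motif, granger = [], []
        for i in range(20):
            motif.append(self._motif(f"T{i}", "m", float(rng.random())))
            granger.append(self._granger(f"T{i}", "m", float(rng.random())))
        regcall.adjust_granger(granger)
        calls = regcall.call_regulators(motif, granger)
        motif_sig = {(m.tf_id, m.module) for m in motif if m.any_window_significant}
        granger_sig = {(g.tf_id, g.module) for g in granger
                       if g.bh_adjusted_p < 0.05}
        called = {(c.tf_id, c.module) for c in calls if c.called}
        assert called == motif_sig & granger_sig

    def test_one_sided_evidence_not_called(self):
        motif = [self._motif("T1", "blue", 0.01)]
        granger = regcall.adjust_granger([self._granger("T2", "blue", 0.001)])
        with pytest.warns(UserWarning, match="only one evidence"):
            calls = regcall.call_regulators(motif, granger)
        assert not any(c.called for c in calls)

    def test_unadjusted_granger_rejected(self):
        with pytest.raises(ValueError, match="adjust_granger"):
            regcall.call_regulators([self._motif("T1", "m", 0.01)],
                                    [self._granger("T1", "m", 0.01)])


def test_meme_round_trip(tmp_path):
    from anhydronet import synthio

    pwms = synthio.make_pwms(["mot_a", "mot_b"], length=6, seed=0)
    path = tmp_path / "motifs.meme"
    regcall.write_meme(pwms, path)
    loaded = regcall.read_meme(path)
    assert [p.motif_id for p in loaded] == ["mot_a", "mot_b"]
    np.testing.assert_allclose(loaded[0].matrix, pwms[0].matrix, atol=1e-5)


def test_pwm_tf_links_threshold():
    import pandas as pd

    rows = [["tfA", "src1", 99, 100, 0, 0, 1, 100, 1, 100, 1e-8, 200.0],
            ["tfA", "src2", 99, 100, 0, 0, 1, 100, 1, 100, 1e-3, 50.0]]
    links = regcall.load_pwm_tf_links(pd.DataFrame(rows), e_threshold=1e-5)
    assert links == {"tfA": {"src1"}}


def test_pwm_validation():
    with pytest.raises(ValueError, match="sum"):
        Pwm("bad", np.full((5, 4), 0.3))
    with pytest.raises(ValueError, match="at least 4"):
        Pwm("short", np.full((2, 4), 0.25))
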