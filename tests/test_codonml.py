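import math

import numpy as np
import pytest
from Bio.Seq import Seq

from dupmeth import codonml as cm
from dupmeth.simulate import simulate_codon_pair


def codons_of(cds):
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


class TestBacktranslate:
    def test_simple_pair(self):
        aln = cm.backtranslate("MK", "MK", "ATGAAA", "ATGAAG")
        assert aln.n_codons == 2
        assert aln.codons1 == ["ATG", "AAA"]
        assert aln.codons2 == ["ATG", "AAG"]

    def test_gapped_column_dropped(self):
        aln = cm.backtranslate("M-K", "MLK", "ATGAAA", "ATGCTGAAG")
        assert aln.n_codons == 2

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            cm.backtranslate("MK", "MK", "ATGAAAC", "ATGAAG")

    def test_internal_stop_raises_with_position(self):
        with pytest.raises(ValueError, match="codon 2"):
            cm.backtranslate("M*K", "MLK", "ATGTAAAAA", "ATGCTGAAG")

    def test_trailing_stop_trimmed(self):
        aln = cm.backtranslate("MK", "MK", "ATGAAATAA", "ATGAAG")
        assert aln.n_codons == 2


class TestNG86:
    def test_identical_sequences(self):
        aln = cm.CodonAlignment(["ATG", "AAA"], ["ATG", "AAA"])
        res = cm.ng86_kaks(aln)
        assert res.ka == 0 and res.ks == 0 and math.isnan(res.omega)

    def test_symmetric_under_order_swap(self):
        c1, c2 = simulate_codon_pair(100, 0.6, 2.0, 0.4, seed=2)
        a = cm.ng86_kaks(cm.CodonAlignment(codons_of(c1), codons_of(c2)))
        b = cm.ng86_kaks(cm.CodonAlignment(codons_of(c2), codons_of(c1)))
        assert a.ka == pytest.approx(b.ka, abs=1e-12)
        assert a.ks == pytest.approx(b.ks, abs=1e-12)

    def test_single_synonymous_difference_matches_site_count_oracle(self):
        # 100 AAA codons vs one AAA->AAG change.  Oracle: enumerate each
        # position's mutations with an independent translator; for Lys
        # codons only the third position's A<->G change is synonymous,
        # so each sequence has exactly 100/3 synonymous sites.
        def syn_sites(codon):
            s = 0.0
            for pos in range(3):
                for nt in "ACGT":
                    if nt == codon[pos]:
                        continue
                    alt = codon[:pos] + nt + codon[pos + 1 :]
                    if str(Seq(alt).translate()) == "*":
                        continue
                    if str(Seq(alt).translate()) == str(Seq(codon).translate()):
                        s += 1 / 3
            return s

        S = 100 * (syn_sites("AAA") + syn_sites("AAG")) / 2
        assert S == pytest.approx(100 / 3)
        expected_ks = -0.75 * math.log1p(-4 * (1 / S) / 3)

        aln = cm.CodonAlignment(["AAA"] * 100, ["AAG"] + ["AAA"] * 99)
        res = cm.ng86_kaks(aln)
        assert res.ka == 0.0
        assert res.ks == pytest.approx(expected_ks, rel=1e-12)

    def test_saturated_distance_is_nan_with_warning(self):
        # all third positions differ synonymously: ps = 100/ (100/3) impossible,
        # so force saturation with a tiny sequence instead
        aln = cm.CodonAlignment(["AAA", "CGA"], ["AAG", "CGG"])
        with pytest.warns(RuntimeWarning):
            res = cm.ng86_kaks(aln)
        assert math.isnan(res.ks)


@pytest.fixture(scope="module")
def uniform_pi():
    return np.full(61, 1 / 61)


class TestRateMatrix:
    @pytest.mark.parametrize("kappa,omega", [(2.0, 0.5), (5.0, 0.1), (0.5, 2.0)])
    def test_rows_sum_to_zero_and_probs_to_one(self, uniform_pi, kappa, omega):
        Q = cm.build_rate_matrix(kappa, omega, uniform_pi)
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-10)
        for t in (0.01, 0.5, 5.0):
            P = cm.transition_matrix(Q, uniform_pi, t)
            assert np.allclose(P.sum(axis=1), 1, atol=1e-10)
            assert (P >= 0).all()

    def test_detailed_balance(self, uniform_pi):
        pi = cm.f3x4_frequencies([codons_of(simulate_codon_pair(200, 0.5, 2, 0.3, seed=4)[0])])
        Q = cm.build_rate_matrix(2.0, 0.4, pi)
        flux = pi[:, None] * Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_scaled_to_one_substitution_per_unit_time(self, uniform_pi):
        Q = cm.build_rate_matrix(2.0, 0.5, uniform_pi)
        assert -(uniform_pi * np.diag(Q)).sum() == pytest.approx(1.0)


class TestLoglikelihood:
    def test_identical_column_small_t_approaches_log_pi(self, uniform_pi):
        aln = cm.CodonAlignment(["ATG"], ["ATG"])
        model = cm.CodonPairML(aln, codon_freqs=uniform_pi)
        ll = model.loglike(1e-8, 2.0, 0.5)
        assert ll == pytest.approx(math.log(1 / 61), abs=1e-6)

    def test_swap_invariance(self, uniform_pi):
        c1, c2 = simulate_codon_pair(150, 0.7, 2.0, 0.5, seed=9)
        m1 = cm.CodonPairML(cm.CodonAlignment(codons_of(c1), codons_of(c2)), uniform_pi)
        m2 = cm.CodonPairML(cm.CodonAlignment(codons_of(c2), codons_of(c1)), uniform_pi)
        assert m1.loglike(0.7, 2.0, 0.5) == pytest.approx(m2.loglike(0.7, 2.0, 0.5), abs=1e-8)

    def test_stationarity_limit_at_large_t(self, uniform_pi):
        c1, c2 = simulate_codon_pair(50, 0.5, 2.0, 0.5, seed=3)
        aln = cm.CodonAlignment(codons_of(c1), codons_of(c2))
        model = cm.CodonPairML(aln, codon_freqs=uniform_pi)
        expected = sum(
            math.log(1 / 61) + math.log(1 / 61) for _ in range(aln.n_codons)
        )
        assert model.loglike(200.0, 2.0, 0.5) == pytest.approx(expected, rel=1e-6)


class TestFit:
    def test_parameter_recovery_at_omega_02(self):
        c1, c2 = simulate_codon_pair(500, 0.8, 2.0, 0.2, seed=42)
        res = cm.CodonPairML(cm.CodonAlignment(codons_of(c1), codons_of(c2))).fit()
        assert res.converged
        assert 0.1 <= res.omega <= 0.35

    def test_free_fit_never_below_fixed_fit(self):
        c1, c2 = simulate_codon_pair(200, 0.6, 2.0, 0.3, seed=7)
        model = cm.CodonPairML(cm.CodonAlignment(codons_of(c1), codons_of(c2)))
        assert model.fit().llf >= model.fit(fixed_omega=0.5).llf - 1e-9

    def test_multistart_reaches_same_optimum(self):
        c1, c2 = simulate_codon_pair(200, 0.6, 2.0, 0.3, seed=8)
        model = cm.CodonPairML(cm.CodonAlignment(codons_of(c1), codons_of(c2)))
        lls = []
        for start in model.STARTS:
            saved = model.STARTS

            class Single(cm.CodonPairML):
                STARTS = (start,)

            single = Single(model.alignment, model.codon_freqs)
            lls.append(single.fit().llf)
            model.STARTS = saved
        assert max(lls) - min(lls) < 1e-3

    def test_identical_alignment_flagged_unidentifiable(self):
        aln = cm.CodonAlignment(["ATG"] * 20, ["ATG"] * 20)
        res = cm.CodonPairML(aln).fit()
        assert not res.identifiable
        assert res.t <= 1e-4
        assert math.isnan(res.omega)

    def test_too_short_alignment_refused(self):
        aln = cm.CodonAlignment(["ATG"] * 5, ["ATG"] * 5)
        with pytest.raises(ValueError, match="codons"):
            cm.CodonPairML(aln).fit()

    def test_summary_mentions_estimates(self):
        c1, c2 = simulate_codon_pair(200, 0.6, 2.0, 0.3, seed=12)
        res = cm.CodonPairML(cm.CodonAlignment(codons_of(c1), codons_of(c2))).fit()
        text = res.summary()
        assert "omega" in text and "log-likelihood" in text
        assert np.isfinite(res.bse["t"])


class TestLRT:
    def test_equal_likelihoods_give_stat_zero(self):
        a = cm.CodonPairMLResults(None, 1, 2, 0.5, -100.0, True, 0.5, True)
        b = cm.CodonPairMLResults(None, 1, 2, 0.4, -100.0, True, None, True)
        stat, p = cm.lrt_purifying(a, b)
        assert stat == 0 and p == 1

    @pytest.mark.parametrize("stat,expected", [(3.84, 0.0500), (6.635, 0.0100)])
    def test_chi_square_reference_points(self, stat, expected):
        a = cm.CodonPairMLResults(None, 1, 2, 0.5, -100.0, True, 0.5, True)
        b = cm.CodonPairMLResults(None, 1, 2, 0.4, -100.0 + stat / 2, True, None, True)
        _, p = cm.lrt_purifying(a, b)
        assert p == pytest.approx(expected, abs=5e-4)

    def test_negative_stat_clipped(self):
        a = cm.CodonPairMLResults(None, 1, 2, 0.5, -99.0, True, 0.5, True)
        b = cm.CodonPairMLResults(None, 1, 2, 0.4, -100.0, True, None, True)
        stat, p = cm.lrt_purifying(a, b)
        assert stat == 0 and p == 1


def test_ng86_ks_and_ml_t_rank_correlated():
    from scipy.stats import spearmanr

    ks_list, t_list = [], []
    for i, ks_target in enumerate((0.1, 0.4, 0.8, 1.3, 1.9)):
        t_true = cm.time_for_target_ks(ks_target, 2.0, 0.3, np.full(61, 1 / 61))
        c1, c2 = simulate_codon_pair(300, t_true, 2.0, 0.3, seed=100 + i)
        aln = cm.CodonAlignment(codons_of(c1), codons_of(c2))
        ks_list.append(cm.ng86_kaks(aln).ks)
        t_list.append(cm.CodonPairML(aln).fit().t)
    rho = spearmanr(ks_list, t_list).statistic
    assert rho > 0.8
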