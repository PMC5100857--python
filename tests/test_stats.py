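import math
from decimal import Decimal, getcontext

import numpy as np
import pytest
from scipy.stats import pearsonr, t as t_dist

from dupmeth import stats

getcontext().prec = 50


class TestShannonSpecificity:
    def test_uniform_has_zero_specificity(self):
        res = stats.shannon_specificity([2.0, 2.0, 2.0, 2.0])
        assert res.H == pytest.approx(2.0)
        assert res.specificity == pytest.approx(0.0)

    def test_onehot_has_specificity_one(self):
        res = stats.shannon_specificity([0, 0, 7.0, 0, 0])
        assert res.H == 0 and res.specificity == 1

    def test_three_to_one_split(self):
        # H = -(3/4)log2(3/4) - (1/4)log2(1/4)
        res = stats.shannon_specificity([3.0, 1.0])
        assert res.H == pytest.approx(0.8113, abs=5e-5)
        assert res.specificity == pytest.approx(0.1887, abs=5e-5)

    def test_all_zero_vector_missing(self):
        res = stats.shannon_specificity([0.0, 0.0])
        assert math.isnan(res.H) and math.isnan(res.specificity)

    def test_permutation_invariant(self):
        v = [5.0, 1.0, 0.5, 2.0]
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(v)
            assert stats.shannon_specificity(perm).H == pytest.approx(
                stats.shannon_specificity(v).H
            )


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert stats.pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert stats.pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_p_value_matches_t_distribution_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        r, p = stats.pearson(x, y)
        t = r * math.sqrt((20 - 2) / (1 - r**2))
        assert p == pytest.approx(2 * t_dist.sf(abs(t), 18), rel=1e-9)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            stats.pearson([1, 1, 1], [1, 2, 3])

    def test_missing_pairs_dropped_listwise(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, 4.1, np.nan]
        r, _ = stats.pearson(x, y)
        r2, _ = stats.pearson([1, 2, 4.0], [1.1, 2.2, 4.1])
        assert r == pytest.approx(r2)


def residual_partial_r(x, y, z):
    """Independent oracle: correlation of residuals after regressing on z."""
    A = np.column_stack([np.ones_like(z), z])

    def resid(v):
        beta, *_ = np.linalg.lstsq(A, v, rcond=None)
        return v - A @ beta

    return pearsonr(resid(x), resid(y)).statistic


class TestPartialCorrelation:
    def test_matches_residual_regression_oracle_on_many_datasets(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = rng.integers(10, 60)
            z = rng.standard_normal(n)
            x = 0.6 * z + rng.standard_normal(n)
            y = -0.4 * z + rng.standard_normal(n)
            r, _ = stats.partial_correlation(x, y, z)
            assert r == pytest.approx(residual_partial_r(x, y, z), abs=1e-10)

    def test_reduces_to_pearson_when_z_uncorrelated(self):
        # construct x, y exactly orthogonal to z
        rng = np.random.default_rng(3)
        z = rng.standard_normal(50)
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        A = np.column_stack([np.ones_like(z), z])
        x -= A @ np.linalg.lstsq(A, x, rcond=None)[0]
        y -= A @ np.linalg.lstsq(A, y, rcond=None)[0]
        r_partial, _ = stats.partial_correlation(x, y, z)
        r_plain, _ = stats.pearson(x, y)
        assert r_partial == pytest.approx(r_plain, abs=1e-10)

    def test_degenerate_control_raises(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            stats.partial_correlation(x, x.copy(), x.copy())


class TestBinnedTrend:
    def test_metric_equal_to_ks_gives_unit_trend(self):
        ks = np.linspace(0.1, 2, 200)
        table, r, p = stats.ks_binned_trend(ks, ks)
        assert r == pytest.approx(1.0)
        assert table["count"].sum() == 200
        assert table["mean_ks"].is_monotonic_increasing

    def test_constant_metric_gives_missing_trend(self):
        ks = np.linspace(0.1, 2, 100)
        _, r, p = stats.ks_binned_trend(ks, np.ones(100))
        assert math.isnan(r) and math.isnan(p)

    def test_planted_negative_slope_detected(self):
        rng = np.random.default_rng(4)
        ks = rng.uniform(0.05, 2, 500)
        metric = 0.8 - 0.3 * ks + 0.1 * rng.standard_normal(500)
        _, r, p = stats.ks_binned_trend(ks, metric)
        assert r < -0.8 and p < 0.001

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            stats.ks_binned_trend([1.0] * 5, [1.0] * 5, n_bins=20)


def fisher_two_sided_oracle(a, b, c, d):
    """Exact enumeration of the conditional hypergeometric distribution."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = Decimal(math.comb(n, c1))
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        k: Decimal(math.comb(r1, k) * math.comb(r2, c1 - k)) / denom for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    cutoff = p_obs * (1 + Decimal("1e-14"))
    return float(sum(v for v in probs.values() if v <= cutoff))


class TestCountTests:
    def test_fisher_reference_value(self):
        _, p = stats.fisher_exact(5, 0, 0, 5)
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_fisher_matches_enumeration_on_all_small_tables(self):
        for n in range(1, 17):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        _, p = stats.fisher_exact(a, b, c, d)
                        assert p == pytest.approx(
                            fisher_two_sided_oracle(a, b, c, d), abs=1e-12
                        ), (a, b, c, d)

    def test_fisher_matches_enumeration_on_larger_margins(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 16, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            _, p = stats.fisher_exact(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-12)

    def test_welch_t_identical_groups(self):
        t, df, p = stats.two_sample_t([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert t == 0 and p == 1

    def test_t_test_needs_two_per_group(self):
        with pytest.raises(ValueError):
            stats.two_sample_t([1.0], [1.0, 2.0])

    def test_proportion_test_matches_r_prop_test(self):
        # prop.test(c(169, 245), c(626, 1633)) gives X-squared = 42.69241,
        # p = 6.40603e-11 (verified against R)
        chi2, p = stats.two_proportion_cc(169, 626, 245, 1633)
        assert chi2 == pytest.approx(42.69241, abs=0.01)
        assert p == pytest.approx(6.40603e-11, rel=1e-4)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            stats.two_proportion_cc(-1, 10, 2, 10)


def bh_stepup_oracle(pvals):
    """Hand implementation of the BH step-up transform."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


class TestBH:
    def test_worked_example(self):
        q = stats.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 50))
            assert np.allclose(stats.bh_fdr(p), bh_stepup_oracle(p), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=100)
        assert (stats.bh_fdr(p) >= p - 1e-15).all()

    def test_empty_input(self):
        assert stats.bh_fdr([]).size == 0


class TestAgeFromKs:
    def test_linearity_and_zero(self):
        assert stats.age_from_ks(0) == 0
        assert stats.age_from_ks(1.0) * 2 == stats.age_from_ks(2.0)

    def test_per_lineage_convention_halves_age(self):
        assert stats.age_from_ks(1.6, per_lineage=True) == stats.age_from_ks(1.6) / 2

    def test_invalid_rate_raises(self):
        with pytest.raises(ValueError):
            stats.age_from_ks(1.0, 0.0)
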