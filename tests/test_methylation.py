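import math
from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dupmeth import methylation as me
from dupmeth.io import GeneModel
from dupmeth.simulate import simulate_site_counts

getcontext().prec = 50


def binom_tail_exact(m, n, p):
    """High-precision upper-tail binomial oracle by direct pmf summation."""
    pd = Decimal(repr(p))
    q = 1 - pd
    return float(sum(Decimal(math.comb(n, k)) * pd**k * q ** (n - k) for k in range(m, n + 1)))


class TestSiteLevel:
    @pytest.mark.parametrize("m,u,expected", [(3, 1, 0.75), (0, 5, 0.0)])
    def test_values(self, m, u, expected):
        assert me.site_level(m, u) == expected

    def test_zero_coverage_is_missing(self):
        assert math.isnan(me.site_level(0, 0))


class TestRegions:
    sizes = {"chr1": 100_000}

    def gene(self, start, end, strand):
        return GeneModel("g", "chr1", strand, start, end)

    def test_plus_strand_promoter_upstream(self):
        regs = me.extract_regions([self.gene(5000, 8000, "+")], self.sizes)
        prom = next(r for r in regs if r.kind == "promoter")
        body = next(r for r in regs if r.kind == "body")
        assert (prom.start, prom.end) == (3000, 5000)
        assert (body.start, body.end) == (5000, 8000)

    def test_minus_strand_promoter_mirrored(self):
        regs = me.extract_regions([self.gene(5000, 8000, "-")], self.sizes)
        prom = next(r for r in regs if r.kind == "promoter")
        assert (prom.start, prom.end) == (8000, 10000)

    def test_promoter_clipped_at_chromosome_start(self):
        regs = me.extract_regions([self.gene(500, 900, "+")], self.sizes)
        prom = next(r for r in regs if r.kind == "promoter")
        assert (prom.start, prom.end) == (0, 500)

    def test_gene_past_chromosome_end_raises(self):
        with pytest.raises(ValueError):
            me.extract_regions([self.gene(99_000, 101_000, "+")], self.sizes)


class TestRegionSummary:
    region = me.Region("g", "promoter", "chr1", "+", 100, 200)

    def summarise(self, pos, m, u, **kw):
        return me.region_summary(np.array(pos), np.array(m), np.array(u), self.region, **kw)

    def test_mean_is_unweighted_over_counted_sites(self):
        s = self.summarise([110, 150], [8, 0], [2, 5])
        assert s.mean_level == pytest.approx(0.4)
        assert s.n_cg == 2

    def test_low_coverage_sites_excluded(self):
        s = self.summarise([110, 150], [1, 3], [0, 1], min_cov=2)
        assert s.n_cg == 1
        assert s.coverage_fraction == pytest.approx(0.5)

    def test_empty_region(self):
        s = self.summarise([], [], [])
        assert s.n_cg == 0 and math.isnan(s.mean_level)


class TestPcgStatistic:
    def test_zero_methylated_gives_one(self):
        assert me.pcg_statistic(0, 20, 0.5) == 1.0

    def test_reference_value_matches_exact_summation(self):
        assert me.pcg_statistic(10, 20, 0.5) == pytest.approx(0.588099, abs=1e-6)
        assert me.pcg_statistic(10, 20, 0.5) == pytest.approx(binom_tail_exact(10, 20, 0.5), abs=1e-12)

    def test_all_methylated_single_term(self):
        assert me.pcg_statistic(20, 20, 0.5) == pytest.approx(0.5**20, rel=1e-9)

    def test_invalid_background_raises(self):
        with pytest.raises(ValueError):
            me.pcg_statistic(1, 10, 0.0)

    @given(st.integers(1, 200), st.floats(0.01, 0.99), st.data())
    @settings(max_examples=30, deadline=None)
    def test_nonincreasing_in_m(self, n, p, data):
        m = data.draw(st.integers(1, n))
        assert me.pcg_statistic(m, n, p) <= me.pcg_statistic(m - 1, n, p) + 1e-12


class TestClassification:
    def summary(self, m_cg, n_cg, cov_frac=1.0):
        s = me.RegionMethylation("g", "promoter", n_cg=n_cg, m_cg=m_cg, n_sites_total=n_cg)
        s.coverage_fraction = cov_frac
        return s

    def test_insufficient_below_ncg_threshold(self):
        assert me.classify_region(self.summary(10, 19), 0.5).klass == "insufficient"

    def test_insufficient_below_coverage_fraction(self):
        assert me.classify_region(self.summary(25, 25, cov_frac=0.5), 0.5).klass == "insufficient"

    def test_extreme_tail_is_methylated(self):
        s = me.classify_region(self.summary(30, 30), 0.5)
        assert s.klass == "methylated" and s.P_CG == pytest.approx(2.0**-30, rel=1e-9)

    def test_zero_methylated_is_unmethylated(self):
        assert me.classify_region(self.summary(0, 30), 0.5).klass == "unmethylated"

    def test_middle_is_intermediate(self):
        assert me.classify_region(self.summary(15, 30), 0.5).klass == "intermediate"

    def test_degenerate_background_clipped(self):
        s = me.classify_region(self.summary(30, 30), 1.0)
        assert 0 <= s.P_CG <= 1

    def test_planted_classes_recovered(self):
        # levels 0.9 vs 0.05 at 30 CpGs, depth 10: classes recover >= 95%
        rng = np.random.default_rng(101)
        correct = total = 0
        for level, want in ((0.9, "methylated"), (0.05, "unmethylated")):
            for _ in range(100):
                m, u = simulate_site_counts(level, 30, 10, rng)
                region = me.Region("g", "promoter", "c", "+", 0, 3000)
                s = me.region_summary(np.arange(30) * 100, m, u, region)
                s = me.classify_region(s, 0.5)
                total += 1
                correct += s.klass == want
        assert correct / total >= 0.95


class TestBackgroundAndSpike:
    def test_half_methylated(self):
        m = np.array([5, 0, 5, 0])
        u = np.array([0, 5, 0, 5])
        assert me.estimate_background(m, u) == 0.5

    def test_low_coverage_ignored(self):
        m = np.array([1, 5])
        u = np.array([0, 0])
        assert me.estimate_background(m, u, min_cov=2) == 1.0

    def test_no_qualifying_sites_raise(self):
        with pytest.raises(ValueError):
            me.estimate_background(np.array([1]), np.array([0]), min_cov=5)

    @pytest.mark.parametrize(
        "m,u,expected", [([0, 0], [10, 10], 0.0), ([5], [995], 0.005)]
    )
    def test_nonconversion(self, m, u, expected):
        assert me.estimate_nonconversion(m, u) == pytest.approx(expected)

    def test_empty_spike_is_missing(self):
        assert math.isnan(me.estimate_nonconversion([], []))


class TestDivergenceIndices:
    def test_divergence_values(self):
        assert me.methylation_divergence(0.4, 0.4) == 0
        assert me.methylation_divergence(0.4, 0.0) == 1
        assert math.isnan(me.methylation_divergence(0.0, 0.0))

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_and_bounded(self, a, b):
        d = me.methylation_divergence(a, b)
        if math.isnan(d):
            assert a + b == 0
        else:
            assert -1 <= d <= 1
            assert d == pytest.approx(-me.methylation_divergence(b, a), abs=1e-12)

    def test_smi_values(self):
        assert me.smi([0.3, 0.3, 0.3]) == 0
        assert me.smi([0, 0, 1]) == 1
        assert me.smi([0.2, 0.4]) == pytest.approx(0.5)
        assert math.isnan(me.smi([0, 0]))

    # levels are ratios of read counts: zero or well away from underflow
    @given(
        st.lists(st.one_of(st.just(0.0), st.floats(1e-6, 1)), min_size=2, max_size=9),
        st.floats(0.1, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_smi_scale_invariant_and_bounded(self, levels, scale):
        v = me.smi(levels)
        if not math.isnan(v):
            assert 0 <= v <= 1 + 1e-12
            assert me.smi([x * scale for x in levels]) == pytest.approx(v, abs=1e-9)

    def test_smi_divergence_mirrors_methylation_divergence(self):
        assert me.smi_divergence(0.5, 0.5) == 0
        assert me.smi_divergence(0.5, 0.0) == 1


class TestConsistency:
    def test_fully_consistent(self):
        ok, member = me.consistent_promoter_divergence(["methylated"] * 9, ["unmethylated"] * 9)
        assert ok and member == 1

    def test_one_flip_breaks_consistency(self):
        c1 = ["methylated"] * 8 + ["unmethylated"]
        c2 = ["unmethylated"] * 8 + ["methylated"]
        assert me.consistent_promoter_divergence(c1, c2) == (False, None)

    def test_one_insufficient_breaks_consistency(self):
        c1 = ["methylated"] * 8 + ["insufficient"]
        c2 = ["unmethylated"] * 9
        assert me.consistent_promoter_divergence(c1, c2) == (False, None)


class TestPromoterComposition:
    @pytest.mark.parametrize(
        "seq,expected", [("CCCC", (1.0, 0)), ("CGCG", (0.5, 2)), ("ATAT", (0.0, 0))]
    )
    def test_values(self, seq, expected):
        assert me.promoter_composition(seq) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            me.promoter_composition("")
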