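"""SFS summary statistics and the weighted block jackknife."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from regsel.genomic_io import PolarizedSiteTable
from regsel.intervals import IntervalSet
from regsel.sfs_stats import (block_jackknife, jackknife_sfs,
                              site_heterozygosity, summarize_region,
                              tajima_constants, tajimas_d, watterson_a1)

from _oracles import pi_sum_all_pairs, tajimas_d_reference


def site_table(pos, derived, called, chrom="chr1", pool="P"):
    pos = np.asarray(pos, dtype=np.int64)
    n = len(pos)
    return PolarizedSiteTable(
        chrom=np.array([chrom] * n, dtype=object), pos=pos, pools=[pool],
        derived=np.asarray(derived, np.int32).reshape(-1, 1),
        called=np.asarray(called, np.int32).reshape(-1, 1),
        status=np.zeros(n, np.int8),
        is_fixed_substitution=np.zeros(n, bool))


class TestSiteHeterozygosity:
    @pytest.mark.parametrize("k,m,expected", [
        (1, 2, 1.0),
        (0, 18, 0.0),
        (2, 4, 2 * 2 * 2 / 12),
    ])
    def test_examples(self, k, m, expected):
        assert site_heterozygosity(k, m) == pytest.approx(expected)

    @given(st.integers(2, 40), st.data())
    def test_symmetric_in_polarity(self, m, data):
        k = data.draw(st.integers(0, m))
        assert site_heterozygosity(k, m) == pytest.approx(
            site_heterozygosity(m - k, m))


class TestWattersonA1:
    @pytest.mark.parametrize("n,expected", [(2, 1.0), (4, 1 + 0.5 + 1 / 3)])
    def test_small_values(self, n, expected):
        assert watterson_a1(n) == pytest.approx(expected)

    def test_n18_matches_direct_summation(self):
        assert watterson_a1(18) == pytest.approx(
            sum(1.0 / i for i in range(1, 18)), abs=1e-12)


class TestTajimasD:
    def test_zero_when_pi_equals_watterson(self):
        n, S = 10, 7
        pi = S / tajima_constants(n)["a1"]
        assert tajimas_d(S, pi, n) == pytest.approx(0.0, abs=1e-12)

    def test_all_singletons_negative(self):
        n, S = 18, 10
        pi = S * site_heterozygosity(1, n)
        assert tajimas_d(S, pi, n) < 0

    def test_intermediate_frequencies_positive(self):
        n, S = 18, 10
        pi = S * site_heterozygosity(9, n)
        assert tajimas_d(S, pi, n) > 0

    def test_matches_reference_formula(self):
        counts = [1, 2]
        n = 4
        pi = sum(site_heterozygosity(k, n) for k in counts)
        assert tajimas_d(2, pi, n) == pytest.approx(
            tajimas_d_reference(counts, n), abs=1e-10)

    def test_undefined_when_no_segregating_sites(self):
        assert math.isnan(tajimas_d(0, 0.0, 18))


class TestSummarizeRegion:
    region = IntervalSet.from_pairs([("chr1", 0, 100)])
    mask = IntervalSet.from_pairs([("chr1", 0, 1000)])

    def test_no_variants(self):
        s = summarize_region(site_table([], [], []), self.region, self.mask, "P")
        assert s.S == 0 and s.theta_pi == 0.0
        assert math.isnan(s.tajimas_d)

    def test_toy_hand_arithmetic(self):
        """n=4, L=100, derived counts {1,2}."""
        t = site_table([10, 20], [1, 2], [4, 4])
        s = summarize_region(t, self.region, self.mask, "P")
        assert s.theta_pi == pytest.approx(0.0116667, abs=1e-6)
        assert s.theta_w == pytest.approx(0.0109091, abs=1e-6)

    def test_doubling_length_halves_theta_pi(self):
        t = site_table([10, 20], [1, 2], [4, 4])
        wide = IntervalSet.from_pairs([("chr1", 0, 200)])
        s1 = summarize_region(t, self.region, self.mask, "P")
        s2 = summarize_region(t, wide, self.mask, "P")
        assert s2.theta_pi == pytest.approx(s1.theta_pi / 2)

    def test_empty_stratum_rejected(self):
        far = IntervalSet.from_pairs([("chr2", 0, 100)])
        with pytest.raises(ValueError, match="empty stratum"):
            summarize_region(site_table([], [], []), far, self.mask, "P")

    def test_fixed_substitutions_not_counted(self):
        t = site_table([10, 20], [1, 4], [4, 4])
        t.is_fixed_substitution[1] = True
        s = summarize_region(t, self.region, self.mask, "P")
        assert s.S == 1


@given(st.integers(2, 6), st.integers(1, 20), st.integers(0, 10**6))
def test_pi_sum_matches_all_pairs_enumeration(n_hap, n_sites, seed):
    """pi_sum equals the explicit average over haplotype-pair Hamming distances."""
    rng = np.random.default_rng(seed)
    haps = rng.integers(0, 2, size=(n_sites, n_hap))
    k = haps.sum(axis=1)
    t = site_table(np.arange(1, n_sites + 1), k, np.full(n_sites, n_hap))
    region = IntervalSet.from_pairs([("chr1", 0, n_sites + 10)])
    s = summarize_region(t, region, region, "P")
    assert s.pi_sum == pytest.approx(pi_sum_all_pairs(haps), abs=1e-12)


def test_theta_pi_and_d_invariant_to_polarity_flips():
    rng = np.random.default_rng(5)
    n, S = 12, 40
    k = rng.integers(1, n, size=S)
    pos = np.arange(1, S + 1)
    region = IntervalSet.from_pairs([("chr1", 0, 1000)])
    flip = rng.random(S) < 0.5
    t1 = site_table(pos, k, np.full(S, n))
    t2 = site_table(pos, np.where(flip, n - k, k), np.full(S, n))
    s1 = summarize_region(t1, region, region, "P")
    s2 = summarize_region(t2, region, region, "P")
    assert s1.theta_pi == pytest.approx(s2.theta_pi, abs=1e-12)
    assert s1.tajimas_d == pytest.approx(s2.tajimas_d, abs=1e-12)


class TestBlockJackknife:
    sizes = {"chr1": 1_000_000}
    region = IntervalSet.from_pairs([("chr1", 0, 1_000_000)])

    def test_constant_statistic_zero_se(self):
        est = block_jackknife(lambda r: 3.5, self.region, self.region,
                              self.sizes, block_bp=100_000)
        assert est.standard_error == pytest.approx(0.0, abs=1e-12)
        assert est.point_estimate == 3.5
        assert est.n_blocks == 10

    def test_zero_weight_blocks_skipped(self):
        narrow = IntervalSet.from_pairs([("chr1", 0, 200_000)])
        est = block_jackknife(lambda r: r.total_length * 1e-6, narrow,
                              narrow, self.sizes, block_bp=100_000)
        assert est.n_blocks == 2  # only the two covered tiles contribute

    def test_too_few_blocks_flagged(self):
        tiny = IntervalSet.from_pairs([("chr1", 0, 50_000)])
        est = block_jackknife(lambda r: 1.0, tiny, tiny, self.sizes,
                              block_bp=100_000)
        assert math.isnan(est.standard_error)

    def test_fast_path_matches_generic(self):
        rng = np.random.default_rng(3)
        S = 500
        pos = np.sort(rng.choice(1_000_000, size=S, replace=False)) + 1
        k = rng.integers(1, 10, size=S)
        t = site_table(pos, k, np.full(S, 10))
        fast = jackknife_sfs(t, self.region, self.region, self.sizes, "P",
                             "theta_pi", block_bp=100_000)

        def stat(region):
            return summarize_region(t, region, self.region, "P").theta_pi

        gen = block_jackknife(stat, self.region, self.region, self.sizes,
                              block_bp=100_000)
        assert fast.point_estimate == pytest.approx(gen.point_estimate)
        assert fast.standard_error == pytest.approx(gen.standard_error)

    def test_weights_sum_to_accessible_length(self):
        t = site_table([10], [1], [4])
        est = jackknife_sfs(t, self.region, self.region, self.sizes, "P",
                            "theta_pi", block_bp=100_000)
        assert est.weights.sum() == self.region.total_length
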