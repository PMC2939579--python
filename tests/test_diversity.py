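"""Diversity statistics, neutrality tests and AMOVA FST.

The published FOXI1 resequencing summaries act as exact desk-scale
oracles: every statistic here reproduces the printed value from the
printed allele-frequency table.
"""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sweepscan.diversity as dv
from sweepscan.fixtures import (AFRICA_HAPLOTYPE_COUNTS, SURVEYED_BP,
                                foxi1_derived_counts, foxi1_expected)

from conftest import make_matrix


@pytest.fixture(scope="module")
def counts():
    return foxi1_derived_counts()


def sfs_of(counts, pop, n=40):
    return dv.SFSCounts.from_counts(counts[pop], n, SURVEYED_BP)


@pytest.mark.parametrize("daf,two_n,expected", [
    (0.58, 40, 23), (0.00, 40, 0), (0.88, 40, 35), (0.5, 2, 1),
])
def test_derived_counts_from_daf(daf, two_n, expected):
    assert dv.derived_counts_from_daf(daf, two_n) == expected


@pytest.mark.parametrize("pop,expected_s", [
    ("Yoruban", 16), ("European", 17), ("Asian", 13), ("All", 22),
])
def test_segregating_sites(counts, pop, expected_s):
    n = 120 if pop == "All" else 40
    assert dv.segregating_sites(sfs_of(counts, pop, n)) == expected_s


def test_monomorphic_sample_has_no_segregating_sites():
    sfs = dv.SFSCounts.from_counts([0, 0, 40], 40, 100)
    assert dv.segregating_sites(sfs) == 0


class TestPairwiseDiversity:
    def test_yoruban_pi_matches_printed_value(self, counts):
        _, pi = dv.pairwise_diversity(sfs_of(counts, "Yoruban"))
        assert round(pi, 4) == 0.0011

    def test_single_site_n2(self):
        k, _ = dv.pairwise_diversity(dv.SFSCounts(2, [1], 10))
        assert k == pytest.approx(1.0)

    def test_matches_pair_enumeration_on_realized_matrix(self, rng):
        al = rng.integers(0, 2, size=(10, 12))
        mat = make_matrix(al)
        sfs = dv.SFSCounts.from_matrix(mat)
        k, _ = dv.pairwise_diversity(sfs)
        pairs = list(combinations(range(10), 2))
        brute = np.mean([(al[i] != al[j]).sum() for i, j in pairs])
        assert k == pytest.approx(brute)


class TestTajimasD:
    @pytest.mark.parametrize("pop,expected", [
        ("Yoruban", 0.487), ("European", 0.485), ("Asian", 1.134), ("All", 0.360),
    ])
    def test_printed_values(self, counts, pop, expected):
        n = 120 if pop == "All" else 40
        assert round(dv.tajimas_D(sfs_of(counts, pop, n)), 3) == expected

    def test_n2_is_identically_zero(self):
        # k = S = S/a1 exactly when n=2
        assert dv.tajimas_D(dv.SFSCounts(2, [1, 1, 1], 10)) == pytest.approx(0.0)

    def test_undefined_without_segregating_sites(self):
        assert np.isnan(dv.tajimas_D(dv.SFSCounts.from_counts([], 10, 10)))


class TestFayWuH:
    @pytest.mark.parametrize("pop,expected", [
        ("Yoruban", -2.928), ("European", 1.600), ("Asian", -1.923), ("All", -0.410),
    ])
    def test_printed_values(self, counts, pop, expected):
        n = 120 if pop == "All" else 40
        assert round(dv.fay_wu_H(sfs_of(counts, pop, n)), 3) == expected

    def test_site_at_half_frequency_contributes_zero(self):
        assert dv.fay_wu_H(dv.SFSCounts(10, [5], 10)) == pytest.approx(0.0)


class TestFuLi:
    @pytest.mark.parametrize("pop", ["Yoruban", "European", "Asian", "All"])
    def test_printed_values(self, counts, pop):
        n = 120 if pop == "All" else 40
        exp = foxi1_expected().loc[pop]
        d, ds, f, fs = dv.fu_li_tests(sfs_of(counts, pop, n))
        assert round(d, 3) == pytest.approx(exp["fu_li_D"], abs=0.0015)
        assert round(ds, 3) == pytest.approx(exp["fu_li_D_star"], abs=0.0015)
        assert round(f, 3) == pytest.approx(exp["fu_li_F"], abs=0.0015)
        assert round(fs, 3) == pytest.approx(exp["fu_li_F_star"], abs=0.0015)

    def test_no_singletons_forces_positive_numerators(self):
        sfs = dv.SFSCounts(10, [3, 4, 5], 10)
        assert all(v > 0 for v in dv.fu_li_tests(sfs))


class TestFuFs:
    @pytest.mark.parametrize("pop,k_obs,expected", [
        ("Yoruban", 12, -0.664), ("European", 12, -0.421), ("Asian", 8, 1.969),
    ])
    def test_printed_values(self, counts, pop, k_obs, expected):
        k, _ = dv.pairwise_diversity(sfs_of(counts, pop))
        assert round(dv.fu_fs(k_obs, k, 40), 3) == expected

    def test_all_distinct_small_theta_is_negative(self):
        assert dv.fu_fs(4, 0.5, 4) < 0

    def test_k_obs_one_is_flagged_infinite(self):
        # P(K >= 1) = 1 exactly, so S' degenerates and Fs diverges
        assert dv.fu_fs(1, 2.0, 4) == float("inf")

    def test_matches_bernoulli_construction_oracle(self):
        """Under the Chinese-restaurant construction K is a sum of
        independent Bernoulli(θ/(θ+i)); its exact Poisson-binomial
        distribution is an independent oracle for the Stirling route."""
        n, theta = 6, 2.0
        probs = np.zeros(n + 1)
        probs[0] = 1.0
        for i in range(n):
            p_new = theta / (theta + i)
            probs = np.roll(probs, 1) * p_new + probs * (1 - p_new)
            # roll introduces wraparound only past index n; safe for k<=n
        pmf = dv.ewens_k_pmf(n, theta)
        assert np.allclose(pmf, probs, atol=1e-12)
        s_prime = probs[3:].sum()
        assert dv.fu_fs(3, theta, n) == pytest.approx(
            np.log(s_prime / (1 - s_prime)))


class TestHaplotypeSummary:
    def test_african_counts_reproduce_printed_k_and_hd(self):
        K, hd = dv.haplotype_summary(AFRICA_HAPLOTYPE_COUNTS)
        assert K == 12
        assert round(hd, 3) == 0.741

    def test_all_identical(self):
        mat = make_matrix(np.zeros((6, 4)))
        assert dv.haplotype_summary(mat) == (1, 0.0)

    def test_all_distinct_gives_hd_exactly_one(self):
        mat = make_matrix(np.triu(np.ones((5, 5))))
        assert dv.haplotype_summary(mat)[1] == pytest.approx(1.0)


class TestFstAmova:
    def test_printed_values(self):
        assert round(dv.fst_amova([23, 8, 14], [40, 40, 40]).fst, 3) == 0.123
        assert round(dv.fst_amova([2, 3, 1], [40, 40, 40]).fst, 3) == -0.012

    def test_equal_frequencies_give_minus_one_over_n_minus_one(self):
        for c in (4, 10, 20):
            res = dv.fst_amova([c, c, c], [40, 40, 40])
            assert res.fst == pytest.approx(-1 / 39)

    def test_private_fixed_allele_gives_fst_one(self):
        assert dv.fst_amova([40, 0, 0], [40, 40, 40]).fst == pytest.approx(1.0)

    def test_identical_fixation_everywhere_is_undefined(self):
        assert np.isnan(dv.fst_amova([40, 40], [40, 40]).fst)

    @given(st.lists(st.integers(0, 20), min_size=2, max_size=5))
    def test_never_exceeds_one(self, cs):
        res = dv.fst_amova(cs, [20] * len(cs))
        if np.isfinite(res.fst):
            assert res.fst <= 1.0 + 1e-12


def test_sfs_and_matrix_routes_agree(rng):
    """π, k, S, D, H from an SFS equal those from a matrix realizing it."""
    al = rng.integers(0, 2, size=(14, 20))
    mat = make_matrix(al)
    sfs_m = dv.SFSCounts.from_matrix(mat, 20)
    counts = (al == 1).sum(axis=0)
    sfs_c = dv.SFSCounts.from_counts(counts, 14, 20)
    for f in (dv.segregating_sites, dv.tajimas_D, dv.fay_wu_H):
        assert f(sfs_m) == pytest.approx(f(sfs_c), nan_ok=True)
    assert dv.pairwise_diversity(sfs_m) == pytest.approx(dv.pairwise_diversity(sfs_c))


def test_statistics_invariant_to_site_order_and_length(counts):
    sfs = sfs_of(counts, "Yoruban")
    perm = dv.SFSCounts(40, np.array(sfs.counts)[::-1], SURVEYED_BP)
    assert dv.tajimas_D(perm) == pytest.approx(dv.tajimas_D(sfs))
    assert dv.fay_wu_H(perm) == pytest.approx(dv.fay_wu_H(sfs))
    longer = dv.SFSCounts(40, sfs.counts, 10 * SURVEYED_BP)
    assert dv.tajimas_D(longer) == pytest.approx(dv.tajimas_D(sfs))


class TestCriticalValues:
    def test_order_statistics_oracle(self):
        lo, hi = dv.neutrality_critical_values(np.arange(1, 101), alpha=0.05)
        assert (lo, hi) == (3, 98)

    def test_small_alpha_reaches_distribution_extremes(self):
        lo, hi = dv.neutrality_critical_values(np.arange(1, 101), alpha=1e-6)
        assert (lo, hi) == (1, 100)

    def test_observed_inside_bounds_is_not_significant(self):
        crit = dv.neutrality_critical_values(np.arange(1, 101), alpha=0.05)
        assert not dv.is_significant(50, crit)
        assert dv.is_significant(99, crit)

    def test_warns_on_tiny_null(self):
        with pytest.warns(UserWarning, match="fewer"):
            dv.neutrality_critical_values(np.arange(10), alpha=0.05)
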