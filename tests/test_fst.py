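"""Unit and property tests for the weighted F_ST estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selnet import SiteCounts, fst_two_groups, multilocus_fst, pairwise_scan, weighted_fst


def brute_force_fst(n, a):
    """Independent plain-loop evaluation of the mean-squares estimator."""
    r = len(n)
    p = [a[i] / n[i] for i in range(r)]
    n_tot = sum(n)
    p_bar = sum(n[i] * p[i] for i in range(r)) / n_tot
    msp = sum(n[i] * (p[i] - p_bar) ** 2 for i in range(r)) / (r - 1)
    msg = sum(n[i] * p[i] * (1 - p[i]) for i in range(r)) / sum(n[i] - 1 for i in range(r))
    n_c = (n_tot - sum(n[i] ** 2 for i in range(r)) / n_tot) / (r - 1)
    if msp == 0 and msg == 0:
        return None
    return (msp - msg) / (msp + (n_c - 1) * msg)


class TestWeightedFst:
    def test_fixed_difference_is_one(self):
        v = weighted_fst(SiteCounts((10, 10), (10, 0)))
        assert v.value == 1.0
        assert v.qualifying

    def test_identical_frequencies_negative(self):
        # MSP = 0 forces the value to -1/(n_c - 1); here n_c = 10
        v = weighted_fst(SiteCounts((10, 10), (5, 5)))
        assert v.value == pytest.approx(-1.0 / 9.0, abs=1e-15)
        assert not v.qualifying

    def test_hand_worked_site(self):
        # MSP = 1.8, MSG = 3.2/18, n_c = 10 -> 0.4771...
        v = weighted_fst(SiteCounts((10, 10), (8, 2)))
        assert v.value == pytest.approx(0.477124183, abs=1e-9)

    def test_monomorphic_site_flagged(self):
        v = weighted_fst(SiteCounts((10, 10), (0, 0)))
        assert v.monomorphic
        assert np.isnan(v.value)
        assert not v.qualifying

    def test_small_population_dropped_then_error(self):
        # one population with a single chromosome is dropped; with only one
        # usable population left the site cannot be evaluated
        with pytest.raises(ValueError, match="fewer than two"):
            weighted_fst(SiteCounts((10, 1), (5, 1)))

    def test_three_population_site(self):
        v = weighted_fst(SiteCounts((10, 10, 10), (8, 2, 5)))
        assert v.value == pytest.approx(brute_force_fst((10, 10, 10), (8, 2, 5)), rel=1e-12)

    def test_oracle_equivalence_random_sites(self):
        """1,000 random sites match the independent brute-force evaluation."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 1000:
            r = rng.integers(2, 5)
            n = tuple(int(x) for x in rng.integers(2, 40, size=r))
            a = tuple(int(rng.integers(0, ni + 1)) for ni in n)
            expected = brute_force_fst(n, a)
            got = weighted_fst(SiteCounts(n, a))
            if expected is None:
                assert got.monomorphic
            else:
                assert got.value == pytest.approx(expected, rel=1e-12)
            checked += 1

    @given(
        n1=st.integers(2, 60), n2=st.integers(2, 60),
        a1=st.integers(0, 60), a2=st.integers(0, 60),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_by_one_and_symmetric(self, n1, n2, a1, a2):
        a1, a2 = min(a1, n1), min(a2, n2)
        v = weighted_fst(SiteCounts((n1, n2), (a1, a2)))
        w = weighted_fst(SiteCounts((n2, n1), (a2, a1)))
        if not v.monomorphic:
            assert v.value <= 1.0 + 1e-12
            assert v.value == pytest.approx(w.value, rel=1e-12, abs=1e-15)
            # value 1 exactly when there is no within-sample variation
            msg_zero = a1 in (0, n1) and a2 in (0, n2)
            assert (v.value == 1.0) == msg_zero

    def test_sample_size_convergence_at_fixed_frequencies(self):
        # duplicating individuals changes the value only through the
        # finite-sample corrections; it converges monotonely as n grows
        values = []
        for mult in (1, 2, 4, 8, 16, 64):
            v = weighted_fst(SiteCounts((10 * mult, 10 * mult), (8 * mult, 2 * mult)))
            values.append(v.value)
        diffs = np.diff(values)
        assert (diffs > 0).all() or (diffs < 0).all()
        assert abs(values[-1] - values[-2]) < abs(values[1] - values[0])


class TestPairwiseScan:
    def test_same_population_both_sides(self, two_pop_panel):
        """Splitting one population against an identical copy gives MSP = 0."""
        panel = two_pop_panel
        # relabel: compare population A against itself is disallowed, so build
        # the counts directly by scanning A vs A via disjoint halves of equal
        # genotypes is not possible here; instead verify the disjointness guard
        with pytest.raises(ValueError, match="share populations"):
            pairwise_scan(panel, {"A"}, {"A", "B"})

    def test_scan_preserves_genome_order(self, two_pop_panel):
        scan = pairwise_scan(two_pop_panel, {"A"}, {"B"})
        for c in scan["chrom"].unique():
            pos = scan.loc[scan["chrom"] == c, "pos"].to_numpy()
            assert (np.diff(pos) > 0).all()

    def test_scan_matches_scalar_estimator(self, tiny_panel):
        scan = pairwise_scan(tiny_panel, {"A"}, {"B"})
        # site s1: A has genotypes (0,1) -> n=4,a=1; B has (2,2) -> n=4,a=4
        v = weighted_fst(SiteCounts((4, 4), (1, 4)))
        assert scan.loc[scan["id"] == "s1", "fst"].item() == pytest.approx(v.value, rel=1e-12)
        # site s2 is 1,1 vs 1,1: identical frequencies 0.5 -> non-qualifying
        row2 = scan.loc[scan["id"] == "s2"]
        assert not row2["qualifying"].item()
        # s3: one A genotype missing -> n_A counts only non-missing chromosomes
        assert scan.loc[scan["id"] == "s3", "n_A"].item() == 2

    def test_all_missing_group_is_skipped(self, tiny_panel):
        panel = tiny_panel
        panel.genotypes[2:, 2] = -1  # all of B missing at s3
        scan = pairwise_scan(panel, {"A"}, {"B"})
        assert scan.loc[scan["id"] == "s3", "status"].item() == 2
        assert scan.attrs["n_skipped"] == 1

    def test_interval_filter_empty_is_not_error(self, two_pop_panel):
        scan = pairwise_scan(two_pop_panel, {"A"}, {"B"}, sites=("99", 0, 1000))
        assert len(scan) == 0

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(5)
        n1 = rng.integers(2, 50, 200)
        n2 = rng.integers(2, 50, 200)
        a1 = rng.integers(0, n1 + 1)
        a2 = rng.integers(0, n2 + 1)
        fst, qual, status = fst_two_groups(n1, a1, n2, a2)
        for i in range(200):
            v = weighted_fst(SiteCounts((int(n1[i]), int(n2[i])), (int(a1[i]), int(a2[i]))))
            if v.monomorphic:
                assert status[i] == 1
            else:
                assert fst[i] == pytest.approx(v.value, rel=1e-12, abs=1e-15)
                assert qual[i] == v.qualifying


def test_multilocus_estimate_between_extremes(two_pop_panel):
    scan = pairwise_scan(two_pop_panel, {"A"}, {"B"})
    est, se = multilocus_fst(scan)
    assert 0.0 < est < 1.0
    assert se > 0.0
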