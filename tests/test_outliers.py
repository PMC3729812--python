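"""Tests for the genome threshold, region scoring, empirical P and network test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from selnet import (
    PopulationSpec,
    Region,
    RegionScore,
    SweepSpec,
    empirical_p,
    genome_threshold,
    network_test,
    pairwise_scan,
    region_fraction,
    sample_null_fractions,
    score_regions,
    simulate_panel,
)


def make_fst_table(chrom, pos, fst, qualifying=None):
    fst = np.asarray(fst, dtype=float)
    if qualifying is None:
        qualifying = ~np.isnan(fst) & (fst > 0)
    return pd.DataFrame(
        {
            "chrom": np.asarray(chrom),
            "pos": np.asarray(pos, dtype=np.int64),
            "id": [f"s{i}" for i in range(len(fst))],
            "fst": fst,
            "qualifying": qualifying,
            "status": np.where(np.isnan(fst), 1, 0),
        }
    )


class TestGenomeThreshold:
    def test_order_statistic_by_construction(self):
        t = genome_threshold(np.arange(1, 101))
        assert t.t99 == 99
        assert (np.arange(1, 101) > t.t99).sum() == 1

    def test_normal_sample_matches_quantile_function(self):
        rng = np.random.default_rng(0)
        t = genome_threshold(rng.standard_normal(1000))
        # MC error of the empirical 99% quantile at n=1000 is ~0.12
        assert t.t99 == pytest.approx(stats.norm.ppf(0.99), abs=0.4)

    def test_degenerate_sample(self):
        t = genome_threshold(np.full(200, 0.3))
        assert t.t99 == 0.3
        assert (np.full(200, 0.3) > t.t99).sum() == 0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            genome_threshold(np.array([]))

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=100, max_size=500))
    @settings(max_examples=50, deadline=None)
    def test_calibration_at_most_one_percent_above(self, values):
        v = np.asarray(values)
        t = genome_threshold(v)
        assert (v > t.t99).mean() <= 0.01


class TestRegionFraction:
    def test_fraction_and_flag(self):
        # 200 qualifying SNPs, 5 above the boundary -> f = 0.025, flagged
        fst = np.concatenate([np.full(195, 0.1), np.full(5, 0.9)])
        table = make_fst_table(["1"] * 200, np.arange(200) * 100, fst)
        thr = genome_threshold(np.linspace(0.01, 0.5, 1000))
        score = region_fraction(Region("1", 0, 50_000), table, thr)
        assert (score.n_qualifying, score.n_high) == (200, 5)
        assert score.fraction == pytest.approx(0.025)
        assert score.flagged

    def test_zero_fraction_not_flagged(self):
        table = make_fst_table(["1"] * 50, np.arange(50) * 100, np.full(50, 0.05))
        thr = genome_threshold(np.linspace(0.01, 0.5, 1000))
        score = region_fraction(Region("1", 0, 50_000), table, thr)
        assert score.fraction == 0.0
        assert not score.flagged

    def test_region_without_qualifying_snps_unevaluable(self):
        table = make_fst_table(["1"] * 10, np.arange(10), np.full(10, -0.1))
        thr = genome_threshold(np.abs(np.linspace(0.01, 0.5, 100)))
        score = region_fraction(Region("1", 0, 50_000), table, thr)
        assert not score.evaluable
        score2 = region_fraction(Region("99", 0, 50_000), table, thr)
        assert not score2.evaluable

    def test_only_qualifying_sites_counted(self):
        fst = np.array([0.9, -0.05, np.nan, 0.9, 0.1])
        table = make_fst_table(["1"] * 5, np.arange(5) * 10, fst)
        thr = genome_threshold(np.linspace(0.01, 0.5, 1000))
        score = region_fraction(Region("1", 0, 50_000), table, thr)
        assert (score.n_qualifying, score.n_high) == (3, 2)


class TestEmpiricalP:
    def test_toy_null_direct_count(self):
        null = np.array([0, 0, 0.01, 0.02, 0.02, 0.03, 0.04, 0.05, 0.06, 0.10])
        score = RegionScore(Region("1", 0, 50_000), 100, 5, 0.05, True)
        out = empirical_p(score, null)
        assert out.empirical_p == pytest.approx(3 / 10)

    def test_zero_fraction_gives_p_one(self):
        null = np.array([0.0, 0.01, 0.5])
        score = RegionScore(Region("1", 0, 50_000), 10, 0, 0.0, False)
        assert empirical_p(score, null).empirical_p == 1.0

    def test_monotone_in_observed_fraction(self):
        rng = np.random.default_rng(1)
        null = rng.random(1000)
        fracs = np.sort(rng.random(50))
        ps = [
            empirical_p(RegionScore(Region("1", 0, 50_000), 10, 0, f, f > 0.01), null).empirical_p
            for f in fracs
        ]
        assert (np.diff(ps) <= 0).all()

    def test_random_windows_redraw_empty(self):
        # SNPs only on the first half of the chromosome: windows landing in
        # the empty half must be redrawn, so every fraction is defined
        table = make_fst_table(["1"] * 500, np.arange(500) * 1000,
                               np.random.default_rng(2).uniform(0.01, 0.5, 500))
        thr = genome_threshold(table["fst"].to_numpy())
        fr = sample_null_fractions(table, thr, {"1": 1_000_000}, n_random=200, seed=3)
        assert len(fr) == 200
        assert np.isfinite(fr).all()

    def test_window_larger_than_genome_errors(self):
        table = make_fst_table(["1"] * 10, np.arange(10), np.full(10, 0.1))
        thr = genome_threshold(np.linspace(0.01, 0.5, 100))
        with pytest.raises(ValueError):
            sample_null_fractions(table, thr, {"1": 10_000}, n_random=10, window=50_000)


class TestNetworkTest:
    def _scores(self, ps):
        return [
            RegionScore(Region("1", i * 100_000, i * 100_000 + 50_000, cluster_id=f"c{i}"),
                        10, 1, 0.1, True, empirical_p=p)
            for i, p in enumerate(ps)
        ]

    def test_no_significant_regions(self):
        res = network_test(self._scores([0.5, 0.9, 0.2]))
        assert res.k == 0
        assert res.network_p == 1.0

    def test_single_hit_closed_form(self):
        res = network_test(self._scores([0.01] + [0.5] * 19))
        assert res.m == 20 and res.k == 1
        assert res.network_p == pytest.approx(1 - 0.95**20, rel=1e-12)

    def test_strong_excess_like_observed_network(self):
        """13 of 54 regions significant at 0.05 is far beyond binomial chance."""
        res = network_test(self._scores([0.01] * 13 + [0.5] * 41))
        assert res.network_p < 1e-4
        exact = sum(
            stats.binom.pmf(j, 54, 0.05) for j in range(13, 55)
        )
        assert res.network_p == pytest.approx(exact, rel=1e-9)

    def test_cluster_collapse(self):
        scores = self._scores([0.01, 0.5, 0.5])
        clustered = [
            RegionScore(
                Region("1", s.region.start, s.region.end, cluster_id="same"),
                10, 1, 0.1, True, empirical_p=s.empirical_p,
            )
            for s in scores
        ]
        res = network_test(clustered)
        assert (res.m, res.k) == (1, 1)
        res2 = network_test(clustered, by_cluster=False)
        assert (res2.m, res2.k) == (3, 1)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            network_test([])


def test_planted_sweep_scores_above_flag_level():
    """A strongly drifted sweep region stands out against a weak background
    in nearly every replicate."""
    sweep = Region("1", 1_000_000, 1_050_000, cluster_id="sweep")
    hits = 0
    n_rep = 25
    for seed in range(n_rep):
        pops = [PopulationSpec("A", "X", 30, 0.05), PopulationSpec("B", "Y", 30, 0.05)]
        panel = simulate_panel(
            pops, 30_000, sweeps=[SweepSpec(sweep, "fst_shift", 0.4)],
            seed=seed, chrom_lengths={"1": 3_000_000},
        )
        scan = pairwise_scan(panel, {"A"}, {"B"})
        thr = genome_threshold(scan.loc[scan["qualifying"], "fst"].to_numpy())
        score = score_regions([sweep], scan, thr)[0]
        hits += score.flagged
    assert hits >= 24
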