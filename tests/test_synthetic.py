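"""Tests for the synthetic panel, track and pileup generators."""

import numpy as np
import pytest
from scipy import stats

from selnet import (
    PopulationSpec,
    Region,
    SweepSpec,
    simulate_ihs_track,
    simulate_panel,
    simulate_pileup,
)


class TestSimulatePanel:
    def test_zero_drift_gives_ancestral_frequencies(self):
        """With F = 0 the Beta degenerates and genotype frequencies are
        binomial draws at exactly the ancestral frequency; with huge samples
        the sample frequency matches it closely."""
        pops = [PopulationSpec("A", "X", 2000, 0.0), PopulationSpec("B", "Y", 2000, 0.0)]
        panel = simulate_panel(pops, 200, seed=3)
        freqs = panel.genotypes.mean(axis=0) / 2.0
        assert np.abs(freqs - panel.ancestral_freqs).max() < 0.05
        # and the two populations agree with each other to binomial noise
        fa = panel.genotypes[:2000].mean(axis=0) / 2
        fb = panel.genotypes[2000:].mean(axis=0) / 2
        assert np.abs(fa - fb).max() < 0.1

    def test_seed_determinism(self):
        pops = [PopulationSpec("A", "X", 20, 0.1)]
        p1 = simulate_panel(pops, 500, seed=9, missing_rate=0.02)
        p2 = simulate_panel(pops, 500, seed=9, missing_rate=0.02)
        assert np.array_equal(p1.genotypes, p2.genotypes)
        assert np.array_equal(p1.pos, p2.pos)
        p3 = simulate_panel(pops, 500, seed=10, missing_rate=0.02)
        assert not np.array_equal(p1.genotypes, p3.genotypes)

    def test_frequency_variance_matches_drift_parameter(self):
        """Across SNPs at (nearly) fixed ancestral p, the population
        frequency variance approaches F·p(1−p) plus the binomial sampling
        term p(1−p)/n_chrom."""
        F, p, n_ind = 0.1, 0.5, 200
        pops = [PopulationSpec("A", "X", n_ind, F)]
        panel = simulate_panel(
            pops, 20_000, seed=17, ancestral_range=(p - 1e-6, p + 1e-6)
        )
        p_hat = panel.genotypes.mean(axis=0) / 2.0
        target = F * p * (1 - p) + p * (1 - p) / (2 * n_ind) * (1 - F)
        assert p_hat.var() == pytest.approx(target, rel=0.10)

    def test_sweep_region_uses_elevated_drift(self):
        sweep = Region("1", 100_000, 150_000)
        pops = [PopulationSpec("A", "X", 50, 0.02), PopulationSpec("B", "Y", 50, 0.02)]
        panel = simulate_panel(
            pops, 20_000,
            sweeps=[SweepSpec(sweep, "fst_shift", 0.4)],
            seed=23, chrom_lengths={"1": 2_000_000},
        )
        inside = (panel.pos >= sweep.start) & (panel.pos < sweep.end)
        fa = panel.genotypes[:50].mean(axis=0) / 2
        fb = panel.genotypes[50:].mean(axis=0) / 2
        gap = (fa - fb) ** 2
        assert gap[inside].mean() > 4 * gap[~inside].mean()

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            PopulationSpec("A", "X", 10, 1.0)
        with pytest.raises(ValueError):
            PopulationSpec("A", "X", 0, 0.1)
        pops = [PopulationSpec("A", "X", 5, 0.1)]
        r1 = Region("1", 0, 100_000)
        r2 = Region("1", 50_000, 150_000)
        with pytest.raises(ValueError, match="overlapping sweep"):
            simulate_panel(
                pops, 100,
                sweeps=[SweepSpec(r1, "fst_shift", 0.3), SweepSpec(r2, "fst_shift", 0.3)],
                seed=0, chrom_lengths={"1": 1_000_000},
            )
        with pytest.raises(ValueError, match="exceed background"):
            simulate_panel(pops, 100, sweeps=[SweepSpec(r1, "fst_shift", 0.05)], seed=0)

    def test_positions_strictly_increasing_and_missing_rate(self):
        pops = [PopulationSpec("A", "X", 30, 0.1)]
        panel = simulate_panel(pops, 5_000, seed=2, missing_rate=0.1)
        for c in np.unique(panel.chrom):
            assert (np.diff(panel.pos[panel.chrom == c]) > 0).all()
        miss = (panel.genotypes == -1).mean()
        assert miss == pytest.approx(0.1, abs=0.01)


class TestSimulateIhsTrack:
    def test_null_scores_standard_normal(self):
        track = simulate_ihs_track({"1": 20_000_000}, density=500, seed=4)
        s = track.df["score"]
        assert len(track) == 10_000
        assert abs(s.mean()) < 4 / np.sqrt(len(s))
        assert s.std() == pytest.approx(1.0, abs=0.05)

    def test_sweep_offset_recovered(self):
        sweep = Region("1", 0, 200_000)  # 1% of a 20 Mb chromosome
        track = simulate_ihs_track(
            {"1": 20_000_000}, density=500,
            sweeps=[SweepSpec(sweep, "ihs_shift", 3.0)], seed=5,
        )
        df = track.df
        inside = df["pos"] < sweep.end
        assert df.loc[inside, "score"].mean() - df.loc[~inside, "score"].mean() == pytest.approx(
            3.0, abs=0.5
        )

    def test_determinism_and_errors(self):
        t1 = simulate_ihs_track({"1": 1_000_000}, 100, seed=6)
        t2 = simulate_ihs_track({"1": 1_000_000}, 100, seed=6)
        assert t1.df.equals(t2.df)
        with pytest.raises(ValueError):
            simulate_ihs_track({}, 100, seed=0)
        with pytest.raises(ValueError):
            simulate_ihs_track({"1": 1_000_000}, 0, seed=0)


class TestSimulatePileup:
    def test_homozygotes_never_called_het(self):
        g = np.zeros(5_000, dtype=int)
        g[2_500:] = 2
        table = simulate_pileup(g, 5.0, seed=7)
        assert (table.calls != 1).all()

    def test_depth_two_heterozygote_detection(self):
        """With exactly 2 reads from a het, both alleles are seen w.p. 1/2."""
        table = simulate_pileup(np.ones(100_000, dtype=int), 2.0, seed=8, fixed_depth=2)
        rate = (table.calls == 1).mean()
        assert rate == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(100_000))

    def test_depth_five_matches_closed_form(self):
        """Detection probability 1 − 2^(1−c) = 0.9375 at c = 5."""
        expected = 1 - 2.0 ** (1 - 5)
        table = simulate_pileup(np.ones(100_000, dtype=int), 5.0, seed=9, fixed_depth=5)
        rate = (table.calls == 1).mean()
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert rate == pytest.approx(expected, abs=4 * se)

    def test_depth_distribution_poisson(self):
        table = simulate_pileup(np.zeros(100_000, dtype=int), 3.3, seed=10)
        kmax = 14
        obs = np.bincount(table.depths, minlength=kmax + 1)
        obs = np.concatenate([obs[:kmax], [obs[kmax:].sum()]])
        exp = stats.poisson.pmf(np.arange(kmax), 3.3) * 100_000
        exp = np.concatenate([exp, [100_000 - exp.sum()]])
        assert stats.chisquare(obs, exp).pvalue > 0.001

    def test_zero_depth_is_missing_and_errors(self):
        table = simulate_pileup(np.ones(10_000, dtype=int), 0.5, seed=11)
        zero = table.depths == 0
        assert zero.any()
        assert (table.calls[zero] == -1).all()
        with pytest.raises(ValueError):
            simulate_pileup(np.ones(10, dtype=int), 0.0)
        with pytest.raises(ValueError):
            simulate_pileup(np.array([0, 3]), 1.0)
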