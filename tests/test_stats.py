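"""Diversity indices, fitness estimation, DFE, piecewise fitness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fluxsel as fx
from fluxsel.diversity import diversity_rate, diversity_series, shannon
from fluxsel.fitness import (dfe, fitness_variance_series, piecewise_fitness,
                             piecewise_from_abundance, relative_fitness)

from conftest import toy_count_table


class TestShannon:
    def test_uniform_equals_log_richness(self):
        assert shannon(np.full(4000, 2.5e-4)) == pytest.approx(np.log(4000))

    def test_single_genotype_zero(self):
        assert shannon([0, 0, 7, 0]) == 0.0

    def test_hand_computed_composition(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.0397 nats
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=5e-5)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.01, max_value=100), min_size=2,
                    max_size=30))
    def test_uniform_maximizes_entropy(self, abund):
        h = shannon(abund)
        assert h <= np.log(len(abund)) + 1e-9
        assert shannon(np.ones(len(abund))) == pytest.approx(np.log(len(abund)))

    def test_depth_invariance_of_composition(self):
        # multinomial resamples of one composition at depths 1e5-1e7 move H
        # by well under 1%
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.full(2000, 5.0))
        h_true = shannon(p)
        for depth in (10**5, 10**6, 10**7):
            counts = rng.multinomial(depth, p)
            assert abs(shannon(counts) - h_true) / h_true < 0.01


class TestDiversityRate:
    def _series(self, h_by_time, reps=(1,)):
        rows = []
        for rep in reps:
            for t, h in h_by_time.items():
                rows.append({"sample_id": f"r{rep}t{t}", "condition": "c",
                             "replicate": rep, "time": float(t), "shannon": h,
                             "richness": 10, "evenness": 0.5})
        return pd.DataFrame(rows).set_index("sample_id")

    def test_constant_diversity_gives_zero_slope(self):
        ser = self._series({t: 5.0 for t in range(0, 241, 24)}, reps=(1, 2))
        r = diversity_rate(ser, "c")
        assert r["slope"] == pytest.approx(0.0, abs=1e-12)
        assert r["ci_low"] <= 1e-12 and r["ci_high"] >= -1e-12

    def test_exact_linear_decline_recovered(self):
        ser = self._series({t: 8.0 - 0.01 * t for t in range(0, 241, 24)})
        r = diversity_rate(ser, "c")
        assert r["slope"] == pytest.approx(-0.01, abs=1e-12)
        assert r["ci_high"] - r["ci_low"] < 1e-10

    def test_replicate_intercepts_absorb_offsets(self):
        # same slope, shifted replicates: pooled fit recovers the slope exactly
        base = {t: 8.0 - 0.01 * t for t in range(0, 241, 24)}
        ser = pd.concat([self._series(base, reps=(1,)),
                         self._series({t: h + 0.7 for t, h in base.items()},
                                      reps=(2,))])
        r = diversity_rate(ser, "c")
        assert r["slope"] == pytest.approx(-0.01, abs=1e-10)

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError):
            diversity_rate(self._series({0: 1.0, 24: 2.0}), "c")


class TestRelativeFitness:
    def _abund(self, counts, times):
        return fx.normalize(toy_count_table(np.asarray(counts), times=times))

    def test_doubling_gives_ln2_over_dt(self):
        # uncentered rate ln2 / 24 = 0.02888/h; recover via centering shift
        # (counts large enough that the log pseudocount is negligible)
        abund = self._abund([[10**6, 2 * 10**6], [10**6, 10**6],
                             [10**6, 10**6]], [0, 24])
        f = relative_fitness(abund, "cond", 0.0, 24.0)
        shift = (f.iloc[0] - f.iloc[1])
        assert shift == pytest.approx(np.log(2) / 24, rel=1e-5)

    def test_centered_mean_is_exactly_zero(self, abundance):
        f = relative_fitness(abundance, "clim")
        assert abs(f.mean()) < 1e-12

    def test_extinct_genotype_is_nan(self):
        abund = self._abund([[1000, 0], [1000, 1000], [500, 600]], [0, 240])
        f = relative_fitness(abund, "cond", 0.0, 240.0)
        assert np.isnan(f.iloc[0]) and np.isfinite(f.iloc[1])

    def test_reversed_interval_rejected(self, abundance):
        with pytest.raises(ValueError):
            relative_fitness(abundance, "clim", 240.0, 0.0)

    def test_telescoping_identity_with_piecewise(self):
        # full-course fitness equals the time-weighted mean of piecewise rates
        rng = np.random.default_rng(4)
        counts = rng.integers(500, 5000, size=(20, 11))
        abund = self._abund(counts, list(range(0, 241, 24)))
        f = relative_fitness(abund, "cond", 0.0, 240.0)
        pw = piecewise_from_abundance(abund, "cond")
        dt = np.diff(np.arange(0, 241, 24.0))
        recombined = (pw * dt).sum(axis=1) / 240.0
        np.testing.assert_allclose(recombined, f, atol=1e-12)


class TestDFE:
    def test_neutral_population_centered_at_zero(self):
        rng = np.random.default_rng(1)
        f = pd.Series(rng.normal(0, 0.002, 3000))
        d = dfe(f, bin_width=0.002)
        centers = (d["bin_edges"][:-1] + d["bin_edges"][1:]) / 2
        assert abs(centers[np.argmax(d["counts"])]) < 0.002

    def test_proportion_changes_sum_to_zero(self):
        rng = np.random.default_rng(2)
        f = pd.Series(rng.normal(0, 0.005, 500), index=[f"g{i}" for i in range(500)])
        p1 = pd.Series(rng.dirichlet(np.ones(500)), index=f.index)
        p2 = pd.Series(rng.dirichlet(np.ones(500)), index=f.index)
        d = dfe(f, 0.002, proportions_t1=p1, proportions_t2=p2)
        assert d["proportion_change"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_static_extreme_exceeds_switch_maximum(self, abundance):
        f_static = relative_fitness(abundance, "clim")
        f_switch = relative_fitness(abundance, "switch")
        assert dfe(f_static)["max"] > dfe(f_switch)["max"]


class TestPiecewiseFitness:
    def test_log_linear_genotype_has_constant_rates(self):
        t = np.arange(0, 241, 24.0)
        log = pd.DataFrame([0.02 * t, 0.01 * t], columns=t)
        pw = piecewise_fitness(log, center=False)
        np.testing.assert_allclose(pw.iloc[0], 0.02, rtol=1e-12)
        np.testing.assert_allclose(pw.iloc[1], 0.01, rtol=1e-12)

    def test_sinusoid_rates_match_finite_difference_oracle(self):
        # closed-form finite differences of sin(2 pi t / 60) sampled at 24 h;
        # the rate sequence repeats every 120 h (5 intervals) and changes sign
        t = np.arange(0, 241, 24.0)
        y = np.sin(2 * np.pi * t / 60)
        log = pd.DataFrame([y, np.zeros_like(t)], columns=t)
        pw = piecewise_fitness(log, center=False)
        oracle = np.diff(y) / 24.0
        np.testing.assert_allclose(pw.iloc[0], oracle, atol=1e-12)
        np.testing.assert_allclose(pw.iloc[0, :-5], pw.iloc[0, 5:], atol=1e-12)
        assert (pw.iloc[0] > 0).any() and (pw.iloc[0] < 0).any()

    def test_interval_centering_zeroes_the_mean(self):
        rng = np.random.default_rng(5)
        log = pd.DataFrame(rng.normal(size=(30, 6)),
                           columns=np.arange(0, 121, 24.0))
        pw = piecewise_fitness(log)
        np.testing.assert_allclose(pw.mean(axis=0), 0.0, atol=1e-12)

    def test_zero_abundance_masks_touching_intervals(self):
        t = np.arange(0, 73, 24.0)
        log = pd.DataFrame([[1, 2, 3, 4.0]], columns=t)
        mask = pd.DataFrame([[False, True, False, False]], columns=t)
        pw = piecewise_fitness(log, zero_mask=mask, center=False)
        assert np.isnan(pw.iloc[0, 0]) and np.isnan(pw.iloc[0, 1])
        assert np.isfinite(pw.iloc[0, 2])


class TestFitnessVariance:
    def test_identical_genotypes_have_zero_variance(self):
        t = np.arange(0, 121, 24.0)
        log = pd.DataFrame(np.tile(0.01 * t, (5, 1)), columns=t)
        pw = piecewise_fitness(log, center=False)
        np.testing.assert_allclose(fitness_variance_series(pw), 0.0, atol=1e-24)

    def test_matches_two_pass_variance(self):
        rng = np.random.default_rng(6)
        pw = pd.DataFrame(rng.normal(size=(40, 7)))
        ours = fitness_variance_series(pw)
        brute = [np.sum((pw[c] - pw[c].mean()) ** 2) / (len(pw) - 1)
                 for c in pw.columns]
        np.testing.assert_allclose(ours, brute, rtol=1e-12)

    def test_switch_variance_oscillates_with_feed_period(self, abundance):
        # alternating selection: variance at intervals within the two feed
        # phases differs systematically in the switch condition
        pw = piecewise_from_abundance(abundance, "switch")
        v = fitness_variance_series(pw).to_numpy()
        # 60 h period over 24 h intervals: the series repeats every 5 intervals
        first, second = v[:5], v[5:]
        assert np.corrcoef(first, second)[0, 1] > 0.5


class TestExtinctionAndTopShare:
    def test_terminal_zero_flags_extinct(self):
        ct = toy_count_table(np.array([[10, 10, 0], [10, 10, 5]]),
                             times=[0, 24, 48])
        abund = fx.normalize(ct)
        flags = fx.extinction(abund, terminal_window=1)
        assert bool(flags.loc["g0", "cond"]) and not bool(flags.loc["g1", "cond"])

    def test_midcourse_dropout_with_recovery_not_extinct(self):
        ct = toy_count_table(np.array([[10, 0, 8], [10, 10, 5]]),
                             times=[0, 24, 48])
        flags = fx.extinction(fx.normalize(ct), terminal_window=1)
        assert not bool(flags.loc["g0", "cond"])
        # widening the terminal window to the full course catches it
        flags3 = fx.extinction(fx.normalize(ct), terminal_window=2)
        assert bool(flags3.loc["g0", "cond"])

    def test_no_common_extinct_set_across_conditions(self, abundance):
        flags = fx.extinction(abundance)
        inter = flags.all(axis=1)
        assert inter.sum() < flags.any(axis=1).sum()

    def test_uniform_population_top_share(self):
        ct = toy_count_table(np.full((4000, 1), 250))
        share = fx.top_genotype_share(fx.normalize(ct), ct.counts.columns[0])
        assert share == pytest.approx(2.5e-4)

    def test_share_bounds(self, abundance):
        for sample in abundance.design.index[:5]:
            share = fx.top_genotype_share(abundance, sample)
            assert 1 / 4000 <= share <= 1.0


class TestDiversitySeries:
    def test_series_matches_direct_shannon(self, abundance):
        ser = diversity_series(abundance)
        sample = abundance.design.index[0]
        assert ser.loc[sample, "shannon"] == pytest.approx(
            shannon(abundance.normalized[sample].to_numpy()))
        assert ((ser["evenness"] >= 0) & (ser["evenness"] <= 1)).all()
        assert (ser["shannon"] <= np.log(ser["richness"])).all()
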