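"""Count filtering, tag aggregation, median-of-ratios normalization, replicate QC."""

import numpy as np
import pandas as pd
import pytest

import fluxsel as fx
from fluxsel.processing import size_factors_median_of_ratios

from conftest import toy_count_table


class TestFilterLibraries:
    def test_strictly_less_than_rule(self):
        # sums {99,999; 100,000; 10^6}: the boundary library is kept
        counts = np.array([[99_999, 100_000, 1_000_000]])
        ct = toy_count_table(counts, times=[0, 24, 48])
        out = fx.filter_libraries(ct, min_reads=100_000)
        assert out.counts.shape[1] == 2
        assert out.meta["dropped_libraries"] == [ct.counts.columns[0]]

    def test_zero_threshold_is_identity(self):
        ct = toy_count_table(np.arange(12).reshape(3, 4) + 1)
        out = fx.filter_libraries(ct, min_reads=0)
        pd.testing.assert_frame_equal(out.counts, ct.counts)

    def test_survivor_count_on_toy_table(self):
        sums = [50, 900, 1000, 1500, 2000]
        ct = toy_count_table(np.array([sums]), times=range(5))
        out = fx.filter_libraries(ct, min_reads=1000)
        assert out.counts.shape[1] == 3

    def test_dropping_everything_is_an_error(self):
        ct = toy_count_table(np.array([[1, 2]]))
        with pytest.raises(ValueError):
            fx.filter_libraries(ct, min_reads=10)

    def test_idempotent(self):
        ct = toy_count_table(np.array([[10, 2000, 3000]]), times=range(3))
        once = fx.filter_libraries(ct, min_reads=1000)
        twice = fx.filter_libraries(once, min_reads=1000)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestSumTags:
    def _tagged(self, up, down):
        idx = pd.MultiIndex.from_product([["gA"], ["up", "down"]],
                                         names=["genotype_id", "tag"])
        design = pd.DataFrame({"condition": "c", "replicate": 1, "time": [0.0],
                               "depth": [up + down]}, index=["s0"])
        counts = pd.DataFrame([[up], [down]], index=idx, columns=["s0"])
        return fx.CountTable(counts, design)

    def test_up_plus_down(self):
        out = fx.sum_tags(self._tagged(10, 15))
        assert out.counts.loc["gA", "s0"] == 25

    def test_missing_tag_needs_permissive_mode(self):
        ct = self._tagged(10, 15)
        ct.counts = ct.counts.iloc[[0]]  # drop the downtag row
        with pytest.raises(ValueError):
            fx.sum_tags(ct)
        out = fx.sum_tags(ct, permissive=True)
        assert out.counts.loc["gA", "s0"] == 10

    def test_genotype_level_input_is_identity(self):
        ct = toy_count_table(np.array([[5, 6], [7, 8]]))
        out = fx.sum_tags(ct)
        pd.testing.assert_frame_equal(out.counts, ct.counts)


class TestFilterGenotypes:
    def test_threshold_semantics(self):
        counts = np.array([[999], [1000], [5000]])
        ct = toy_count_table(counts)
        out = fx.filter_genotypes(ct, min_aggregate=1000)
        assert len(out.counts) == 2
        assert out.meta["dropped_genotypes"] == ["g0"]

    def test_zero_threshold_is_identity(self):
        ct = toy_count_table(np.arange(8).reshape(4, 2))
        pd.testing.assert_frame_equal(
            fx.filter_genotypes(ct, 0).counts, ct.counts)

    def test_matches_brute_force_row_filter(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 400, size=(30, 6))
        ct = toy_count_table(counts, times=range(6))
        out = fx.filter_genotypes(ct, min_aggregate=1000)
        expected = [f"g{i}" for i in range(30) if counts[i].sum() >= 1000]
        assert list(out.counts.index) == expected

    def test_idempotent(self):
        ct = toy_count_table(np.arange(20).reshape(5, 4) * 100)
        once = fx.filter_genotypes(ct, 1000)
        twice = fx.filter_genotypes(once, 1000)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestNormalize:
    def test_identical_samples_have_unit_factors(self):
        counts = np.tile([[100], [200], [300]], (1, 2))
        ct = toy_count_table(counts)
        abund = fx.normalize(ct)
        np.testing.assert_allclose(abund.size_factors, 1.0)

    def test_doubled_sample_hand_computed_factors(self):
        # B = 2A elementwise => factors {1/sqrt2, sqrt2}; normalized equal
        a = np.array([100, 250, 600])
        counts = np.column_stack([a, 2 * a])
        ct = toy_count_table(counts)
        abund = fx.normalize(ct)
        np.testing.assert_allclose(abund.size_factors,
                                   [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)
        np.testing.assert_allclose(abund.normalized.iloc[:, 0],
                                   abund.normalized.iloc[:, 1], rtol=1e-12)

    def test_equivariant_to_depth_rescaling(self):
        # multiplying one sample's depth by a constant changes every
        # normalized abundance by one shared factor only (normalized
        # abundances are defined up to a global scale), so all between-sample
        # ratios — the substance of every downstream statistic — are unchanged
        rng = np.random.default_rng(3)
        counts = rng.integers(50, 500, size=(40, 5))
        ct = toy_count_table(counts, times=range(5))
        scaled = counts.astype(float).copy()
        scaled[:, 2] *= 7.0
        ct2 = toy_count_table(scaled.astype(int), times=range(5))
        n1 = fx.normalize(ct).normalized.to_numpy()
        n2 = fx.normalize(ct2).normalized.to_numpy()
        ratio = n2 / n1
        np.testing.assert_allclose(ratio, ratio[0, 0], rtol=1e-9)

    def test_matches_pydeseq2_size_factors(self):
        # independent oracle: DESeq2's median-of-ratios as shipped in pydeseq2
        pydeseq2 = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(11)
        counts = rng.negative_binomial(20, 0.1, size=(60, 8))
        ct = toy_count_table(counts, times=range(8))
        ours = size_factors_median_of_ratios(ct.counts)
        _, theirs = pydeseq2.deseq2_norm(counts.T.astype(float))
        theirs = theirs / np.exp(np.mean(np.log(theirs)))
        np.testing.assert_allclose(ours.to_numpy(), theirs, rtol=1e-9)

    def test_fallback_when_no_all_positive_genotype(self):
        counts = np.array([[0, 10], [10, 0]])
        ct = toy_count_table(counts)
        with pytest.warns(RuntimeWarning, match="total-count"):
            abund = fx.normalize(ct)
        assert (abund.size_factors > 0).all()

    def test_log_uses_pseudocount_for_zeros(self):
        counts = np.array([[0, 100], [100, 100]])
        ct = toy_count_table(counts)
        abund = fx.normalize(ct, pseudocount=0.5)
        assert np.isfinite(abund.log.to_numpy()).all()
        assert abund.normalized.iloc[0, 0] == 0.0


class TestReplicateQC:
    def _abund(self, shuffle_rep=None, seed=0):
        rng = np.random.default_rng(seed)
        times = list(range(0, 121, 24))
        base = rng.normal(5, 1, size=(50, len(times)))
        cols, names, meta = [], [], []
        for rep in (1, 2, 3):
            block = base + rng.normal(0, 0.05, size=base.shape)
            if rep == shuffle_rep:
                block = block[rng.permutation(50)]
            cols.append(block)
            for t in times:
                names.append(f"c_r{rep}_t{t}")
                meta.append({"condition": "c", "replicate": rep,
                             "time": float(t), "depth": 1000})
        design = pd.DataFrame(meta, index=names)
        counts = pd.DataFrame(
            np.exp(np.concatenate(cols, axis=1)).astype(int) + 1,
            index=[f"g{i}" for i in range(50)], columns=names)
        ct = fx.CountTable(counts, design)
        return fx.normalize(ct)

    def test_consistent_replicates_all_retained(self):
        abund, report = fx.replicate_qc(self._abund(), min_correlation=0.8)
        assert not report["flagged"].any()
        assert abund.log.shape[1] == 18

    def test_label_permuted_replicate_flagged_and_dropped(self):
        abund, report = fx.replicate_qc(self._abund(shuffle_rep=2),
                                        min_correlation=0.8)
        flagged = report[report["flagged"]]
        assert list(flagged["replicate"]) == [2]
        assert set(abund.design["replicate"]) == {1, 3}

    def test_single_replicate_condition_is_error(self):
        abund = self._abund()
        solo = abund.drop_samples([s for s in abund.design.index
                                   if not s.startswith("c_r1")])
        with pytest.raises(ValueError):
            fx.replicate_qc(solo)


class TestPipelineOrder:
    def test_process_counts_runs_all_stages(self, scenario):
        table, _ = scenario
        abund = fx.process_counts(table)
        assert abund.log.shape[1] == 99  # deep libraries: none dropped
        assert (abund.size_factors > 0).all()
        # geometric mean of the size factors is pinned at 1
        assert np.exp(np.mean(np.log(abund.size_factors))) == pytest.approx(1.0)
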