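import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelcnv.errors import BatchSizeError, DegenerateSampleError
from panelcnv.io import CoverageTable
from panelcnv.normalize import (
    FLOOR_LOG2,
    Log2RatioMatrix,
    batch_median_log2,
    cluster_x_samples,
    fractional_coverage,
    normalize_batch,
    normalize_x,
    x_summaries,
)

from conftest import make_intervals


def make_cov(totals, n_x=0):
    totals = np.asarray(totals, dtype=float)
    n_samples, n_intervals = totals.shape
    ivs = make_intervals(n_intervals, x_from=n_intervals - n_x if n_x else None)
    samples = [f"S{i}" for i in range(n_samples)]
    return CoverageTable(intervals=ivs, samples=samples, totals=totals)


def matrix_with_x_summaries(values, n_x=8):
    """A Log2RatioMatrix whose per-sample X summaries equal ``values``."""
    n = len(values)
    n_auto = 4
    ivs = make_intervals(n_auto + n_x, x_from=n_auto)
    ratios = np.zeros((n, n_auto + n_x))
    for s, v in enumerate(values):
        ratios[s, n_auto:] = v
    return Log2RatioMatrix(
        intervals=ivs, samples=[f"S{i}" for i in range(n)],
        ratios=ratios, masked=np.zeros(n_auto + n_x, dtype=bool),
    )


class TestFractionalCoverage:
    def test_simple_fractions(self):
        cov = make_cov([[100, 300, 600]] * 3)
        frac = fractional_coverage(cov)
        np.testing.assert_allclose(frac[0], [0.1, 0.3, 0.6])

    def test_rows_sum_to_one(self, clean_batch):
        frac = fractional_coverage(clean_batch.coverage)
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=25, derandomize=True)
    def test_scale_invariance(self, k):
        base = np.array([[100.0, 300, 600], [200, 100, 50], [10, 20, 30]])
        scaled = base.copy()
        scaled[1] *= k
        np.testing.assert_allclose(
            fractional_coverage(make_cov(base))[1],
            fractional_coverage(make_cov(scaled))[1],
            rtol=1e-12,
        )

    def test_all_zero_sample_names_sample(self):
        cov = make_cov([[1, 2, 3], [0, 0, 0], [4, 5, 6]])
        with pytest.raises(DegenerateSampleError, match="S1"):
            fractional_coverage(cov)


class TestBatchMedianLog2:
    def _log2(self, fractions):
        fractions = np.asarray(fractions, dtype=float)
        ivs = make_intervals(fractions.shape[1])
        return batch_median_log2(
            fractions, ivs, [f"S{i}" for i in range(fractions.shape[0])]
        )

    def test_theoretical_single_copy_ratios(self):
        # one sample at 1.5x / 0.5x the batch median of an interval
        fractions = np.ones((5, 2))
        fractions[0, 0] = 1.5
        fractions[0, 1] = 0.5
        m = self._log2(fractions)
        assert m.ratios[0, 0] == pytest.approx(np.log2(1.5))  # 0.585, 3 copies
        assert m.ratios[0, 1] == pytest.approx(-1.0)          # 1 copy
        assert m.ratios[1, 0] == 0.0

    def test_zero_median_interval_is_masked(self):
        fractions = np.ones((4, 3))
        fractions[:, 1] = 0.0
        m = self._log2(fractions)
        assert m.masked.tolist() == [False, True, False]
        assert np.isnan(m.ratios[:, 1]).all()

    def test_zero_fraction_maps_to_floor(self):
        fractions = np.ones((4, 2))
        fractions[2, 0] = 0.0
        m = self._log2(fractions)
        assert m.ratios[2, 0] == FLOOR_LOG2

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(BatchSizeError):
            self._log2(np.ones((2, 4)))

    def test_median_normalization_property(self):
        rng = np.random.default_rng(0)
        fractions = rng.lognormal(0, 1, size=(7, 30))
        m = self._log2(fractions)
        med = np.median(2.0 ** m.ratios, axis=0)
        np.testing.assert_allclose(med, 1.0, atol=1e-9)

    def test_scale_invariance_end_to_end(self, clean_batch):
        cov = clean_batch.coverage
        scaled = CoverageTable(
            intervals=cov.intervals, samples=cov.samples, totals=cov.totals.copy()
        )
        scaled.totals[3] *= 7.5
        _, a, _ = normalize_batch(cov)
        _, b, _ = normalize_batch(scaled)
        np.testing.assert_allclose(a.ratios[3], b.ratios[3], rtol=1e-9)


def brute_force_two_cluster_cost(values):
    """Best total absolute deviation over every bipartition, with each
    group's medoid chosen optimally within the group."""
    n = len(values)
    best = np.inf
    for mask in range(1, 2 ** (n - 1)):  # non-empty, complement non-empty
        g1 = [values[i] for i in range(n) if mask >> i & 1]
        g2 = [values[i] for i in range(n) if not mask >> i & 1]
        cost = 0.0
        for g in (g1, g2):
            cost += min(sum(abs(v - m) for v in g) for m in g)
        best = min(best, cost)
    return best


class TestClusterXSamples:
    def test_mixed_batch_clusters_and_sexes(self):
        m = matrix_with_x_summaries([-0.97, -1.02, 0.01, 0.03])
        res = cluster_x_samples(m)
        assert not res.degenerate
        assert res.assignment.tolist() == [0, 0, 1, 1]
        assert res.predicted_sex == ["male", "male", "female", "female"]
        # shift re-centres each cluster on zero
        assert res.shift[0] == pytest.approx(np.median([-0.97, -1.02]) * -1)
        assert res.shift[2] == pytest.approx(np.median([0.01, 0.03]) * -1)

    def test_single_sex_batch_is_degenerate(self):
        m = matrix_with_x_summaries([0.00, 0.01, 0.02, 0.03])
        res = cluster_x_samples(m)
        assert res.degenerate
        assert set(res.predicted_sex) == {"indeterminate"}

    def test_two_samples_split_into_own_medoids(self):
        m = matrix_with_x_summaries([-1.0, 0.0])
        res = cluster_x_samples(m)
        assert res.predicted_sex == ["male", "female"]

    def test_no_x_intervals_skips(self):
        ivs = make_intervals(6)
        m = Log2RatioMatrix(
            intervals=ivs, samples=["a", "b", "c"],
            ratios=np.zeros((3, 6)), masked=np.zeros(6, dtype=bool),
        )
        res = cluster_x_samples(m)
        assert not res.has_x
        assert np.all(res.shift == 0)

    def test_exhaustive_bipartition_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(2, 9)
            # half the batches bimodal, half unimodal
            if rng.random() < 0.5:
                vals = np.concatenate(
                    [rng.normal(-1, 0.1, n // 2 + 1), rng.normal(0, 0.1, n - n // 2 - 1)]
                )[:n]
            else:
                vals = rng.normal(0, 0.4, n)
            m = matrix_with_x_summaries(list(vals))
            res = cluster_x_samples(m, min_separation=0.0)
            impl_cost = sum(
                min(abs(v - mv) for mv in res.medoid_values) for v in vals
            )
            assert impl_cost == pytest.approx(brute_force_two_cluster_cost(list(vals)))

    def test_outlier_probes_trimmed_from_summary(self):
        m = matrix_with_x_summaries([0.0, 0.0, 0.0], n_x=20)
        m.ratios[0, -1] = 9.0  # one wild probe must not move the summary
        assert x_summaries(m)[0] == pytest.approx(0.0)


class TestNormalizeX:
    def test_cluster_median_recentred_to_zero(self):
        m = matrix_with_x_summaries([-0.97, -1.02, 0.01, 0.03])
        res = cluster_x_samples(m)
        corrected = normalize_x(m, res)
        post = x_summaries(corrected)
        for cluster in (0, 1):
            members = post[res.assignment == cluster]
            assert np.median(members) == pytest.approx(0.0, abs=1e-9)

    def test_autosomes_untouched(self):
        m = matrix_with_x_summaries([-1.0, -1.0, 0.0, 0.0])
        m.ratios[:, :4] = 0.25
        corrected = normalize_x(m, cluster_x_samples(m))
        np.testing.assert_array_equal(corrected.ratios[:, :4], 0.25)

    def test_female_cluster_already_centered_is_unchanged(self):
        m = matrix_with_x_summaries([-1.0, -1.0, 0.0, 0.0])
        corrected = normalize_x(m, cluster_x_samples(m))
        np.testing.assert_allclose(corrected.ratios[2, 4:], 0.0, atol=1e-12)
        np.testing.assert_allclose(corrected.ratios[0, 4:], 0.0, atol=1e-12)

    def test_mixed_sex_batch_centres_all_samples(self, mixed_batch):
        pre, post, res = normalize_batch(mixed_batch.coverage)
        pre_summ = x_summaries(pre)
        assert pre_summ.max() - pre_summ.min() > 0.5  # two dosage clusters
        post_summ = x_summaries(post)
        assert np.abs(post_summ).max() < 0.1
        truth = [mixed_batch.sexes[s] for s in post.samples]
        assert res.predicted_sex == truth
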