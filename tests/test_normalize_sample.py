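import numpy as np
import pytest

from metanorm.datamodel import PeakTable
from metanorm.normalize import normalize, apply_model
from metanorm.normalize.sample import (
    contrast_normalize,
    cubic_splines,
    cyclic_loess,
    li_wong,
    linear_baseline,
    mstus,
    pqn,
    quantile_normalize,
    _invariant_set,
)
from conftest import proportional_table


def _table(x, prefix="f"):
    p, n = np.asarray(x).shape
    return PeakTable(
        [f"{prefix}{i}" for i in range(p)], [f"s{j}" for j in range(n)], np.asarray(x, float)
    )


class TestLinearBaseline:
    def test_pure_scaling_removed(self):
        x = np.array([[1.0, 3.0], [2.0, 6.0], [4.0, 12.0]])
        out, _ = linear_baseline(_table(x))
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1], rtol=1e-12)

    def test_hand_computed_factors(self):
        x = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 6.0, 9.0]])
        # baseline = row medians (2,4,6); mean(b)=4; column means (2,4,6)
        out, _ = linear_baseline(_table(x))
        factors = np.array([4 / 2, 4 / 4, 4 / 6])
        np.testing.assert_allclose(out.values, x * factors[None, :], rtol=1e-12)

    def test_frozen_reference_uses_stored_mean(self):
        x = np.array([[1.0, 3.0], [2.0, 6.0], [4.0, 12.0]])
        _, model = linear_baseline(_table(x))
        new = _table(np.array([[10.0, 10.0], [10.0, 10.0], [10.0, 10.0]]))
        out, _ = linear_baseline(new, model=model)
        # stored mean baseline mean(b) from training, not from `new`
        expected = 10.0 * (model.payload["mean_baseline"] / 10.0)
        np.testing.assert_allclose(out.values, expected)

    def test_zero_sample_mean_rejected(self):
        with pytest.raises(ValueError, match="zero sample mean"):
            linear_baseline(_table([[0.0, 1.0], [0.0, 2.0]]))


class TestPqn:
    def test_pure_dilution_removed_exactly(self, rng):
        t, d = proportional_table(rng)
        out, _ = pqn(t)
        for j in range(1, t.n_samples):
            np.testing.assert_allclose(out.values[:, j], out.values[:, 0], rtol=1e-10)

    def test_median_quotient_one_after_normalization(self, small_table):
        out, model = pqn(small_table)
        ref = np.asarray(model.payload["reference"])
        q = out.values / ref[:, None]
        np.testing.assert_allclose(np.median(q, axis=0), 1.0, rtol=1e-12)

    def test_dilution_factors_recovered(self, rng):
        t, d = proportional_table(rng, p=200, n=12)
        _, model = pqn(t)
        est = np.array([model.payload["dilution_factors"][s] for s in t.sample_ids])
        corr = np.corrcoef(est, d)[0, 1]
        assert corr > 0.999

    def test_frozen_consistency(self, small_table):
        out, model = pqn(small_table)
        again, _ = pqn(small_table, model=model)
        np.testing.assert_allclose(again.values, out.values, rtol=1e-9)

    def test_zero_reference_rejected(self):
        x = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="zero median reference"):
            pqn(_table(x), pre_integral=False)


class TestMstus:
    def test_complete_matrix_all_features_shared(self, small_table):
        _, model = mstus(small_table)
        assert model.payload["shared_features"] == small_table.feature_ids

    def test_shared_totals_equal_after_normalization(self, small_table):
        out, model = mstus(small_table)
        idx = [small_table.feature_ids.index(f) for f in model.payload["shared_features"]]
        totals = out.values[idx].sum(axis=0)
        np.testing.assert_allclose(totals, totals[0], rtol=1e-12)

    def test_missing_flagged_feature_excluded(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        pre_mask = np.zeros_like(x, dtype=bool)
        pre_mask[2, 1] = True  # f2 was missing pre-imputation
        t = _table(x)
        out, model = mstus(t, shared_mask=pre_mask)
        assert model.payload["shared_features"] == ["f0", "f1", "f3"]
        totals = x[[0, 1, 3]].sum(axis=0)  # (11, 14)
        expected = x / totals[None, :] * totals.mean()
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_no_shared_features_rejected(self):
        x = np.ones((2, 2))
        mask = np.array([[True, False], [False, True]])
        with pytest.raises(ValueError, match="no features shared"):
            mstus(_table(x), shared_mask=mask)


class TestQuantile:
    def test_sorted_columns_identical(self, small_table):
        out, _ = quantile_normalize(small_table)
        s = np.sort(out.values, axis=0)
        for j in range(1, out.values.shape[1]):
            np.testing.assert_array_equal(s[:, j], s[:, 0])

    def test_two_sample_hand_example(self):
        out, _ = quantile_normalize(_table([[1.0, 3.0], [2.0, 4.0]]))
        np.testing.assert_allclose(out.values, [[2.0, 2.0], [3.0, 3.0]])

    def test_idempotent(self, small_table):
        once, _ = quantile_normalize(small_table)
        t2 = PeakTable(once.feature_ids, once.sample_ids, once.values)
        twice, _ = quantile_normalize(t2)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)

    def test_ties_share_mean_of_rank_means(self):
        # column 0 has a 2-way tie spanning ranks 1-2
        x = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out, _ = quantile_normalize(_table(x))
        ref = np.sort(x, axis=0).mean(axis=1)  # (5.5, 10.5, 17.5)
        assert out.values[0, 0] == out.values[1, 0] == pytest.approx(ref[:2].mean())

    def test_frozen_application_maps_to_reference(self, rng, small_table):
        out, model = quantile_normalize(small_table)
        again, _ = quantile_normalize(small_table, model=model)
        np.testing.assert_allclose(again.values, out.values, rtol=1e-9)


class TestCyclicLoess:
    def test_identical_columns_unchanged(self, rng):
        col = np.exp(rng.normal(5, 1, 60))
        x = np.column_stack([col, col, col])
        out, _ = cyclic_loess(_table(x))
        np.testing.assert_allclose(out.values, x, rtol=1e-9)

    def test_constant_offset_removed(self, rng):
        col = np.exp(rng.normal(5, 1, 200))
        x = np.column_stack([col, 3.0 * col])
        out, _ = cyclic_loess(_table(x))
        M = np.log2(out.values[:, 0]) - np.log2(out.values[:, 1])
        assert np.abs(M).mean() < 1e-2

    def test_nonpositive_rejected_by_default(self):
        with pytest.raises(ValueError, match="positive"):
            cyclic_loess(_table([[0.0, 1.0], [2.0, 3.0]]))


class TestContrast:
    def test_identical_columns_unchanged(self, rng):
        col = np.exp(rng.normal(5, 1, 80))
        x = np.column_stack([col] * 4)
        out, _ = contrast_normalize(_table(x))
        np.testing.assert_allclose(out.values, x, rtol=1e-8)

    def test_rotation_orthonormal(self):
        from scipy.linalg import helmert

        for n in (3, 5, 8):
            Q = helmert(n, full=True)
            np.testing.assert_allclose(Q @ Q.T, np.eye(n), atol=1e-12)
            np.testing.assert_allclose(Q[0], np.full(n, 1 / np.sqrt(n)))

    def test_zeros_replaced_no_nan(self, rng):
        x = np.abs(rng.normal(100, 20, (50, 4)))
        x[0, 0] = 0.0
        out, _ = contrast_normalize(_table(x))
        assert np.isfinite(out.values).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            contrast_normalize(_table([[1.0, 2.0], [3.0, 4.0]]))


class TestCubicSplines:
    def test_sample_equal_to_baseline_identity(self, rng):
        col = np.exp(rng.normal(5, 1, 300))
        x = np.column_stack([col] * 4)  # baseline == every column
        out, _ = cubic_splines(_table(x))
        np.testing.assert_allclose(out.values, x, rtol=1e-6)

    def test_monotone_distortion_corrected(self, rng):
        base = np.exp(rng.normal(5, 1, 500))
        distorted = base ** 1.2
        x = np.column_stack([base] * 5 + [distorted])
        out, _ = cubic_splines(_table(x))
        # compare sorted log-quantiles of the corrected column with baseline
        lb = np.sort(np.log2(np.exp(np.log(base))))
        lc = np.sort(np.log2(out.values[:, 5]))
        slope = np.polyfit(np.sort(np.log2(base)), lc, 1)[0]
        assert 0.95 <= slope <= 1.05

    def test_monotone_order_preserved(self, rng):
        col = np.exp(rng.normal(5, 1, 300))
        x = np.column_stack([col, col * rng.uniform(0.8, 1.2)])
        out, _ = cubic_splines(_table(x))
        for j in range(2):
            order = np.argsort(x[:, j])
            assert (np.diff(out.values[order, j]) >= -1e-9).all()


class TestLiWong:
    def test_baseline_sample_unchanged(self, rng):
        x = np.exp(rng.normal(5, 1, (100, 5)))
        t = _table(x)
        out, model = li_wong(t)
        base = model.payload["baseline_sample"]
        j = t.sample_ids.index(base)
        np.testing.assert_allclose(out.values[:, j], x[:, j], rtol=1e-12)

    def test_doubled_sample_mapped_onto_baseline(self, rng):
        base = np.exp(rng.normal(5, 1, 400))
        x = np.column_stack([base, 2.0 * base, base * 1.001])
        out, model = li_wong(_table(x), span=0.3)
        j = 1
        rel = np.abs(out.values[:, j] - base) / base
        assert np.median(rel) < 0.05

    def test_invariant_set_iteration_terminates(self, rng):
        s = rng.normal(size=500)
        b = s + rng.normal(scale=0.2, size=500)
        idx, used = _invariant_set(s, b, 0.05, 10, adapt=True)
        assert idx.size >= 10
        assert used >= 0.05

    def test_strict_mode_errors_on_tiny_invariant_set(self, rng):
        s = rng.normal(size=200)
        b = rng.normal(size=200)  # unrelated ranks
        with pytest.raises(ValueError, match="prd_threshold"):
            _invariant_set(s, b, 0.001, 50, adapt=False)


class TestCommonProperties:
    PURE_DILUTION_EXACT = ["pqn", "quantile", "linear_baseline", "mstus"]

    @pytest.mark.parametrize("method", PURE_DILUTION_EXACT)
    def test_pure_dilution_collapses_columns(self, rng, method):
        t, _ = proportional_table(rng)
        out, _ = normalize(t, method)
        for j in range(1, t.n_samples):
            np.testing.assert_allclose(out.values[:, j], out.values[:, 0], rtol=1e-9)

    @pytest.mark.parametrize(
        "method", ["linear_baseline", "pqn", "mstus", "quantile", "cubic_splines", "li_wong"]
    )
    def test_frozen_two_path_consistency_exact(self, rng, method):
        x = np.exp(rng.normal(5, 1, (60, 6)))
        t = _table(x)
        out, model = normalize(t, method)
        again = apply_model(t, model)
        np.testing.assert_allclose(again.values, out.values, rtol=1e-9)

    @pytest.mark.parametrize("method", ["cyclic_loess", "contrast"])
    def test_frozen_two_path_consistency_loose(self, rng, method):
        # jointly-fitted methods: the frozen path adjusts against the stored
        # reference spectrum, so only approximate agreement is expected, and
        # only on data with the dilution+noise structure these methods assume
        spectrum = np.exp(rng.normal(5, 1, 200))
        d = np.exp(rng.normal(0, 0.3, 6))
        x = spectrum[:, None] * d[None, :] * np.exp(0.1 * rng.standard_normal((200, 6)))
        t = _table(x)
        out, model = normalize(t, method)
        again = apply_model(t, model)
        la, lo = np.log2(again.values), np.log2(out.values)
        assert np.corrcoef(la.ravel(), lo.ravel())[0, 1] > 0.999
        assert np.median(np.abs(la - lo)) < 0.05

    @pytest.mark.parametrize(
        "method",
        ["linear_baseline", "pqn", "mstus", "quantile", "cyclic_loess",
         "contrast", "cubic_splines", "li_wong"],
    )
    def test_shape_and_ids_preserved(self, small_table, method):
        out, _ = normalize(small_table, method)
        assert out.shape == small_table.shape
        assert out.feature_ids == small_table.feature_ids
        assert out.sample_ids == small_table.sample_ids
        assert out.method == method
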