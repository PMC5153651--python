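import numpy as np
import pytest

from metanorm import benchmark as bench
from metanorm.datamodel import PeakTable, SampleMetadata
from metanorm.evaluate import REDUCED_SVM_GRID
from metanorm.synthetic import SyntheticSpec, generate


def _study(n_case=20, n_control=25, p=10, seed=0):
    rng = np.random.default_rng(seed)
    n = n_case + n_control
    ids = [f"s{i}" for i in range(n)]
    labels = ["case"] * n_case + ["control"] * n_control
    x = np.exp(rng.normal(5, 1, (p, n)))
    table = PeakTable([f"f{i}" for i in range(p)], ids, x)
    meta = SampleMetadata.from_records(ids, labels)
    return table, meta


class TestSplit:
    def test_published_design_counts(self):
        # 1005 samples (469 vs 536), training 400 vs 500 -> 105 validation
        table, meta = _study(n_case=469, n_control=536, p=2)
        train, valid = bench.split_train_validation(
            table, meta, train_counts={"case": 400, "control": 500}, seed=0
        )
        assert len(valid) == 105
        assert len(train) == 900

    def test_same_seed_same_split(self):
        table, meta = _study()
        a = bench.split_train_validation(table, meta, valid_frac=0.2, seed=5)
        b = bench.split_train_validation(table, meta, valid_frac=0.2, seed=5)
        assert a == b
        c = bench.split_train_validation(table, meta, valid_frac=0.2, seed=6)
        assert a != c

    def test_stratification_preserves_ratio(self):
        table, meta = _study(n_case=30, n_control=60)
        train, valid = bench.split_train_validation(table, meta, valid_frac=0.2, seed=1)
        train_labels = meta.labels(train)
        assert abs((train_labels == "case").sum() - 24) <= 1


class TestAllocation:
    def test_largest_remainder_hand_toy(self):
        # quotas 2.5/1.5/1.0: floors (2,1,1), leftover goes to largest remainder
        out = bench.allocate_largest_remainder(np.array([5, 3, 2]), 5)
        assert out.tolist() == [3, 1, 1]
        assert out.sum() == 5

    def test_allocation_never_exceeds_cluster_size(self):
        out = bench.allocate_largest_remainder(np.array([1, 9]), 8)
        assert out[0] <= 1 and out.sum() == 8

    def test_infeasible_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            bench.allocate_largest_remainder(np.array([2, 2]), 5)


class TestSubsample:
    def test_paper_size_ladder(self):
        scheme = bench.SubsampleScheme()
        counts = scheme.class_counts({"case": 500, "control": 400})
        assert [c["case"] for c in counts] == [50, 100, 150, 200, 250, 300, 350, 400, 450, 500]
        assert [c["control"] for c in counts] == [40, 80, 120, 160, 200, 240, 280, 320, 360, 400]

    def test_nested_chain_and_sizes(self):
        table, meta = _study(n_case=30, n_control=40, p=8, seed=2)
        scheme = bench.SubsampleScheme(fractions=(0.2, 0.5, 1.0), kmeans_k=4, nested=True, seed=2)
        subs = bench.kmeans_subsample(table, meta, meta.sample_ids, scheme)
        assert [len(s) for s in subs] == [14, 35, 70]
        assert set(subs[0]) <= set(subs[1]) <= set(subs[2])
        labels = meta.labels(subs[0])
        assert (labels == "case").sum() == 6  # 0.2 * 30

    def test_non_nested_mode_runs(self):
        table, meta = _study(n_case=20, n_control=20, p=6, seed=3)
        scheme = bench.SubsampleScheme(fractions=(0.5, 1.0), kmeans_k=3, nested=False, seed=3)
        subs = bench.kmeans_subsample(table, meta, meta.sample_ids, scheme)
        assert [len(s) for s in subs] == [20, 40]

    def test_seed_reproducible(self):
        table, meta = _study(n_case=24, n_control=24, p=6, seed=4)
        scheme = bench.SubsampleScheme(fractions=(0.5,), kmeans_k=3, seed=9)
        a = bench.kmeans_subsample(table, meta, meta.sample_ids, scheme)
        b = bench.kmeans_subsample(table, meta, meta.sample_ids, scheme)
        assert a == b


@pytest.fixture(scope="module")
def mini_bench():
    spec = SyntheticSpec(n_features=120, n_per_class=(24, 24), n_qc=0,
                         missing_total_frac=0.0, drift_slope=0.0, seed=21)
    table, meta, _ = generate(spec)
    scheme = bench.SubsampleScheme(fractions=(0.5, 1.0), kmeans_k=4, seed=2)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = bench.run_benchmark(
            table, meta, methods=["pqn", "auto", "log"], scheme=scheme,
            valid_frac=0.2, svm_grid=REDUCED_SVM_GRID, seed=2,
        )
    return table, meta, scheme, res


class TestRunBenchmark:
    def test_cell_grid_complete(self, mini_bench):
        _, _, _, res = mini_bench
        assert res.auc_matrix.shape == (3, 2)
        assert res.errors == {}
        assert len(res.cells) == 6

    def test_rerun_same_seed_identical(self, mini_bench):
        import warnings

        table, meta, scheme, res = mini_bench
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res2 = bench.run_benchmark(
                table, meta, methods=["pqn", "auto", "log"], scheme=scheme,
                valid_frac=0.2, svm_grid=REDUCED_SVM_GRID, seed=2,
            )
        np.testing.assert_array_equal(res.auc_matrix, res2.auc_matrix)

    def test_cells_cached_and_resumable(self, mini_bench, tmp_path):
        import warnings

        table, meta, scheme, res = mini_bench
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            first = bench.run_benchmark(
                table, meta, methods=["pqn"], scheme=scheme, valid_frac=0.2,
                svm_grid=REDUCED_SVM_GRID, seed=2, out_dir=str(tmp_path),
            )
            again = bench.run_benchmark(
                table, meta, methods=["pqn"], scheme=scheme, valid_frac=0.2,
                svm_grid=REDUCED_SVM_GRID, seed=2, out_dir=str(tmp_path),
            )
        assert (tmp_path / "cells").exists()
        np.testing.assert_array_equal(first.auc_matrix, again.auc_matrix)


class TestDistance:
    def test_hand_example(self):
        m = np.array([[0.6, 0.7], [0.5, 0.9]])
        d_m = bench.method_distance(m, "manhattan")
        d_e = bench.method_distance(m, "euclidean")
        assert d_m[0, 1] == pytest.approx(0.3)
        assert d_e[0, 1] == pytest.approx(np.sqrt(0.1**2 + 0.2**2))

    def test_metric_axioms(self, rng):
        m = rng.random((16, 10))
        for metric in ("manhattan", "euclidean"):
            d = bench.method_distance(m, metric)
            np.testing.assert_allclose(d, d.T)
            np.testing.assert_allclose(np.diag(d), 0, atol=1e-12)
            # triangle inequality on all triples
            for i in range(16):
                for j in range(16):
                    assert d[i, j] <= d[i].max() + 1e-9
                    for k in range(0, 16, 5):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_loop_oracle_agreement(self, rng):
        m = rng.random((16, 10))
        d_m = bench.method_distance(m, "manhattan")
        d_e = bench.method_distance(m, "euclidean")
        for i in range(16):
            for j in range(16):
                assert d_m[i, j] == pytest.approx(sum(abs(m[i] - m[j])), abs=1e-12)
                assert d_e[i, j] == pytest.approx(np.sqrt(((m[i] - m[j]) ** 2).sum()), abs=1e-12)

    def test_missing_cells_imputed_with_warning(self, rng):
        m = rng.random((4, 5))
        m[1, 2] = np.nan
        with pytest.warns(UserWarning, match="imputed"):
            d = bench.method_distance(m)
        assert np.isfinite(d).all()


class TestWard:
    def test_tight_pairs_merge_first(self):
        pts = np.array([[0.0], [0.01], [10.0], [10.02], [100.0]])
        from scipy.spatial.distance import cdist

        d = cdist(pts, pts)
        Z = bench.ward_cluster(d)
        first_two = {frozenset(Z[0, :2].astype(int)), frozenset(Z[1, :2].astype(int))}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_heights_non_decreasing(self, rng):
        m = rng.random((10, 6))
        Z = bench.ward_cluster(bench.method_distance(m))
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            bench.ward_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))


def _toy_auc_matrix():
    """16 methods: one dominant, one worst, one 'occasional top' in the middle."""
    rng = np.random.default_rng(0)
    m = 0.70 + 0.01 * rng.standard_normal((16, 10))
    m[0] = 0.95  # dominant
    m[15] = 0.50  # uniformly worst
    m[7, 4] = 0.93  # middle method that reaches the top tertile once
    return m


class TestCategorize:
    def test_three_levels_ranked(self):
        m = _toy_auc_matrix()
        methods = [f"m{i}" for i in range(16)]
        d = bench.method_distance(m)
        grouping = bench.categorize(bench.ward_cluster(d), m, methods, distance_matrix=d)
        assert grouping.assignment["m0"] == "A"
        assert grouping.assignment["m15"] == "C"

    def test_occasional_top_lands_in_b1(self):
        m = _toy_auc_matrix()
        methods = [f"m{i}" for i in range(16)]
        d = bench.method_distance(m)
        grouping = bench.categorize(bench.ward_cluster(d), m, methods, distance_matrix=d)
        assert grouping.assignment["m7"] == "B1"

    def test_invariant_to_method_order(self):
        m = _toy_auc_matrix()
        methods = [f"m{i}" for i in range(16)]
        d = bench.method_distance(m)
        g1 = bench.categorize(bench.ward_cluster(d), m, methods, distance_matrix=d)
        perm = np.random.default_rng(3).permutation(16)
        m2 = m[perm]
        methods2 = [methods[i] for i in perm]
        d2 = bench.method_distance(m2)
        g2 = bench.categorize(bench.ward_cluster(d2), m2, methods2, distance_matrix=d2)
        assert g1.assignment == g2.assignment

    def test_too_few_methods_rejected(self):
        m = np.array([[0.9, 0.8], [0.5, 0.6]])
        with pytest.raises(ValueError):
            bench.categorize(np.zeros((1, 4)), m, ["a", "b"])


class TestReport:
    def test_report_contents(self, tmp_path):
        m = _toy_auc_matrix()
        methods = [f"method_{i}" for i in range(16)]
        d = bench.method_distance(m)
        grouping = bench.categorize(
            bench.ward_cluster(d), m, methods, fractions=list(np.arange(1, 11) / 10),
            distance_matrix=d,
        )
        path = bench.report(grouping, None, str(tmp_path), figures=False)
        text = open(path).read()
        for meth in methods:
            assert meth in text
        assert text.count("|") > 100  # 16 x 10 AUC table
        assert ";" in text  # embedded Newick
        for g in ("Group A", "Group B1", "Group B2", "Group C"):
            assert g in text
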