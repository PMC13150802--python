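import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from sensorselect import (
    ClassLabeling,
    PerformanceRecord,
    PipelineConfig,
    build_ruler,
    chi_squared_score,
    discretize,
    eliminate_one,
    eta_sweep,
    generate_dataset,
    pairwise_deltas,
    planted_recovery_spec,
    run_elimination,
    select_working_point,
    weighted_chi_squared_score,
)
from sensorselect.selection import EliminationTrace, IterationRecord


def labeling_from(labels, K=None):
    labels = np.asarray(labels)
    K = K or labels.max() + 1
    return ClassLabeling(labels, tuple(f"c{k}" for k in range(K)))


def make_trace(errors_percent):
    """Build a minimal trace with the given e(l) for l = p..1."""
    p = len(errors_percent)
    iterations = []
    sensors = [f"S{j}" for j in range(p)]
    for i, l in enumerate(range(p, 0, -1)):
        rec = PerformanceRecord(l, (errors_percent[i] / 100,), errors_percent[i],
                                1.0, 1.0, (0.9, 0.1), 2)
        surviving = tuple(sensors[: l])
        removed = surviving[-1] if l > 1 else None
        iterations.append(IterationRecord(i, l, surviving, removed, rec))
    return EliminationTrace(tuple(iterations))


class TestBuildRuler:
    def test_voronoi_midpoint_two_classes(self):
        values = np.array([0.0, 0.0, 2.0, 2.0])
        ruler = build_ruler(values, labeling_from([0, 0, 1, 1]), mode="voronoi")
        np.testing.assert_allclose(ruler.thresholds, [1.0])
        assert ruler.class_order == (0, 1)

    def test_voronoi_consecutive_midpoints(self):
        values = np.array([0.0, 0.0, 1.0, 1.0, 4.0, 4.0])
        ruler = build_ruler(values, labeling_from([0, 0, 1, 1, 2, 2]), mode="voronoi")
        np.testing.assert_allclose(ruler.thresholds, [0.5, 2.5])

    def test_classes_reordered_by_increasing_mean(self):
        values = np.array([4.0, 4.0, 0.0, 0.0, 1.0, 1.0])
        ruler = build_ruler(values, labeling_from([0, 0, 1, 1, 2, 2]), mode="voronoi")
        assert ruler.class_order == (1, 2, 0)
        assert ruler.interval_classes == (1, 2, 0)

    def test_qda1d_equal_variances_reduce_to_midpoints(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(0, 0.3, size=8)
        values = np.concatenate([noise[:4], 10.0 + noise[:4]])  # identical spreads
        lab = labeling_from([0] * 4 + [1] * 4)
        v = build_ruler(values, lab, mode="voronoi")
        q = build_ruler(values, lab, mode="qda1d")
        np.testing.assert_allclose(q.thresholds, v.thresholds, atol=1e-9)

    def test_qda1d_threshold_shifts_toward_tight_class(self):
        # the low-variance class keeps a narrower zone than the midpoint
        values = np.array([-0.01, 0.0, 0.01, 6.0, 10.0, 14.0])
        lab = labeling_from([0, 0, 0, 1, 1, 1])
        q = build_ruler(values, lab, mode="qda1d", inflation="unadjusted")
        assert 0.0 < q.thresholds[0] < 5.0

    def test_identical_means_deduplicated(self):
        values = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        lab = labeling_from([0, 0, 1, 1, 2, 2])
        ruler = build_ruler(values, lab, mode="voronoi")
        assert len(ruler.thresholds) == 1
        assert np.all(np.diff(ruler.thresholds) > 0)


class TestDiscretize:
    def test_interval_membership(self):
        values = np.array([0.0, 0.0, 1.0, 1.0, 4.0, 4.0])
        ruler = build_ruler(values, labeling_from([0, 0, 1, 1, 2, 2]), mode="voronoi")
        bins = discretize(np.array([-3.0, 1.2, 9.0]), ruler)
        np.testing.assert_array_equal(bins, [0, 1, 2])

    def test_value_on_threshold_goes_left(self):
        values = np.array([0.0, 0.0, 1.0, 1.0, 4.0, 4.0])
        ruler = build_ruler(values, labeling_from([0, 0, 1, 1, 2, 2]), mode="voronoi")
        np.testing.assert_array_equal(discretize(np.array([0.5, 2.5]), ruler), [0, 1])


class TestChiSquared:
    def test_perfect_two_class_separation(self):
        # contingency [[5,0],[0,5]] -> chi2 = n(K-1) = 10
        bins = np.array([0] * 5 + [1] * 5)
        labels = np.array([0] * 5 + [1] * 5)
        assert chi_squared_score(bins, labels) == pytest.approx(10.0)

    def test_independent_bins_score_zero(self):
        bins = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        labels = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        assert chi_squared_score(bins, labels) == pytest.approx(0.0)

    def test_perfect_three_class_separation(self):
        bins = np.repeat([0, 1, 2], 3)
        labels = np.repeat([0, 1, 2], 3)
        assert chi_squared_score(bins, labels) == pytest.approx(18.0)

    def test_degenerate_single_bin_scores_zero(self):
        assert chi_squared_score(np.zeros(6), np.repeat([0, 1], 3)) == 0.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        bins = rng.integers(0, 3, 40)
        labels = rng.integers(0, 2, 40)
        table = np.zeros((3, 2))
        np.add.at(table, (bins, labels), 1)
        if np.all(table.sum(axis=1) > 0) and np.all(table.sum(axis=0) > 0):
            expected = chi2_contingency(table, correction=False).statistic
            assert chi_squared_score(bins, labels) == pytest.approx(expected)

    def test_invariant_under_class_relabeling(self):
        rng = np.random.default_rng(2)
        bins = rng.integers(0, 3, 30)
        labels = rng.integers(0, 3, 30)
        perm = np.array([2, 0, 1])
        assert chi_squared_score(bins, labels) == pytest.approx(
            chi_squared_score(bins, perm[labels])
        )

    def test_invariant_under_monotone_transform_preserving_bins(self):
        values = np.array([0.0, 0.1, 1.0, 1.1, 4.0, 4.1])
        lab = labeling_from([0, 0, 1, 1, 2, 2])
        ruler = build_ruler(values, lab, mode="voronoi")
        transformed = np.exp(values)
        ruler_t = build_ruler(transformed, lab, mode="voronoi")
        # exp preserves ordering, so interval membership is identical
        np.testing.assert_array_equal(
            discretize(values, ruler), discretize(transformed, ruler_t)
        )
        assert chi_squared_score(discretize(values, ruler), lab.labels) == pytest.approx(
            chi_squared_score(discretize(transformed, ruler_t), lab.labels)
        )


class TestWeightedChiSquared:
    def test_two_classes_equals_uniform_score(self):
        values = np.array([0.0, 0.2, 2.0, 2.2])
        lab = labeling_from([0, 0, 1, 1])
        ruler = build_ruler(values, lab, mode="voronoi")
        bins = discretize(values, ruler)
        deltas = pairwise_deltas(values, lab)
        assert weighted_chi_squared_score(bins, lab.labels, deltas) == pytest.approx(
            chi_squared_score(bins, lab.labels)
        )

    def test_equal_deltas_give_unweighted_mean(self):
        bins = np.repeat([0, 1, 2], 3)
        labels = np.repeat([0, 1, 2], 3)
        deltas = {(0, 1): 2.0, (0, 2): 2.0, (1, 2): 2.0}
        score, details = weighted_chi_squared_score(
            bins, labels, deltas, return_details=True
        )
        pair_stats = [d.chi2 for d in details]
        assert score == pytest.approx(np.mean(pair_stats))
        assert all(d.weight == pytest.approx(1 / 3) for d in details)

    def test_inverse_delta_weight_normalisation(self):
        bins = np.repeat([0, 1, 2], 3)
        labels = np.repeat([0, 1, 2], 3)
        deltas = {(0, 1): 1.0, (0, 2): 3.0, (1, 2): 3.0}
        _, details = weighted_chi_squared_score(bins, labels, deltas, return_details=True)
        weights = {d.pair: d.weight for d in details}
        assert weights[(0, 1)] == pytest.approx(0.6)
        assert weights[(0, 2)] == pytest.approx(0.2)
        assert weights[(1, 2)] == pytest.approx(0.2)

    def test_zero_delta_capped_not_infinite(self):
        bins = np.repeat([0, 1, 2], 3)
        labels = np.repeat([0, 1, 2], 3)
        deltas = {(0, 1): 0.0, (0, 2): 1.0, (1, 2): 1.0}
        score, details = weighted_chi_squared_score(
            bins, labels, deltas, scale=1.0, return_details=True
        )
        assert np.isfinite(score)
        weights = {d.pair: d.weight for d in details}
        assert weights[(0, 1)] > 0.99  # confusable pair dominates


class TestEliminateOne:
    def test_removes_minimum_score(self):
        assert eliminate_one({"a": 10.0, "b": 0.1, "c": 7.0}) == "b"

    def test_tie_broken_by_sensor_order(self):
        assert eliminate_one({"a": 5.0, "b": 1.0, "c": 1.0}) == "b"

    def test_single_survivor_rejected(self):
        with pytest.raises(ValueError):
            eliminate_one({"a": 1.0})


class TestRunElimination:
    def test_three_sensor_trace_structure(self, fast_config):
        spec = planted_recovery_spec(K=3, p=3, n_informative=2, separation=5.0, seed=0)
        table, lab = generate_dataset(spec)
        trace = run_elimination(table, lab, fast_config)
        assert [it.n_sensors for it in trace.iterations] == [3, 2, 1]
        removed = [it.removed for it in trace.iterations]
        assert removed[-1] is None
        assert len([r for r in removed if r is not None]) == 2

    def test_surviving_sets_strictly_nested(self, fast_config):
        spec = planted_recovery_spec(K=4, p=6, n_informative=2, separation=4.0, seed=1)
        table, lab = generate_dataset(spec)
        trace = run_elimination(table, lab, fast_config)
        all_sensors = set(table.sensor_ids)
        seen_removed = []
        for prev, nxt in zip(trace.iterations[:-1], trace.iterations[1:]):
            assert set(nxt.surviving) == set(prev.surviving) - {prev.removed}
            seen_removed.append(prev.removed)
        final = set(trace.iterations[-1].surviving)
        assert set(seen_removed) | final == all_sensors
        assert len(seen_removed) == len(set(seen_removed))

    def test_deterministic_given_seed(self, fast_config):
        spec = planted_recovery_spec(K=3, p=5, n_informative=2, separation=4.0, seed=2)
        table, lab = generate_dataset(spec)
        t1 = run_elimination(table, lab, fast_config)
        t2 = run_elimination(table, lab, fast_config)
        for a, b in zip(t1.iterations, t2.iterations):
            assert a.removed == b.removed
            assert a.record == b.record

    def test_planted_sensors_survive(self, fast_config):
        spec = planted_recovery_spec(K=5, p=10, n_informative=2, separation=8.0, seed=3)
        table, lab = generate_dataset(spec)
        trace = run_elimination(table, lab, fast_config)
        assert set(trace.surviving_at(2)) == set(spec.informative)


class TestWorkingPoint:
    def test_zero_error_prefers_single_sensor(self):
        trace = make_trace([0.0, 0.0, 0.0])
        assert select_working_point(trace, 3.0).l_star == 1

    def test_enumeration_example(self):
        # e = (10, 2, 1.9)% for l = 1, 2, 3 and eta = 3 -> J = (13, 8, 10.9)
        trace = make_trace([1.9, 2.0, 10.0])
        wp = select_working_point(trace, 3.0)
        assert wp.l_star == 2
        assert wp.cost[1] == pytest.approx(13.0)
        assert wp.cost[2] == pytest.approx(8.0)
        assert wp.cost[3] == pytest.approx(10.9)

    def test_eta_zero_minimises_error_with_parsimony_ties(self):
        trace = make_trace([5.0, 1.0, 1.0, 4.0])
        wp = select_working_point(trace, 0.0)
        assert wp.l_star == 2  # smaller l on tied minimal error

    def test_cost_identity(self):
        trace = make_trace([3.0, 1.0, 2.0, 8.0])
        for eta in (0.0, 0.5, 3.0, 7.7):
            wp = select_working_point(trace, eta)
            errors = trace.errors_by_count()
            for l, J in wp.cost.items():
                assert J - errors[l] == pytest.approx(eta * l)

    def test_selected_sensors_match_trace(self):
        trace = make_trace([9.0, 0.5, 0.6, 0.7])
        wp = select_working_point(trace, 3.0)
        assert wp.sensor_ids == trace.surviving_at(wp.l_star)

    def test_negative_eta_rejected(self):
        with pytest.raises(ValueError):
            select_working_point(make_trace([1.0, 2.0]), -1.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 100.0), min_size=2, max_size=12),
        st.integers(0, 2**31 - 1),
    )
    def test_matches_exhaustive_enumeration_and_sweep_monotone(self, errors, seed):
        trace = make_trace(errors)
        rng = np.random.default_rng(seed)
        eta = float(rng.uniform(0, 10))
        wp = select_working_point(trace, eta)
        # exhaustive oracle
        by_count = trace.errors_by_count()
        costs = [(by_count[l] + eta * l, l) for l in sorted(by_count)]
        assert wp.l_star == min(costs)[1]
        # l*(eta) never increases as the penalty grows
        ls = [l for _, l in eta_sweep(trace, 0.0, 10.0, 0.25)]
        assert all(b <= a for a, b in zip(ls, ls[1:]))
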