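"""The iterative region-scaling framework: scores, weights, ROI, schedule, fusion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peddrs.inverse_solvers import SolverSpec
from peddrs.peddrs_core import (
    PeddrsConfig,
    ROIBox,
    attenuation_coefficient,
    evaluate_cos,
    evaluate_l2,
    final_distribution,
    gaussian_filter_iterations,
    IterationRecord,
    nodes_in_box,
    probabilistic_distribution,
    probability_weights,
    refresh_index,
    roi_box,
    roi_center,
    roi_covariance,
    run_peddrs,
    update_size,
)


class TestScores:
    def test_l2_error_cases(self):
        A = np.eye(2)
        idx = np.array([0, 1])
        B = np.array([0.0, 1.0])
        assert evaluate_l2(A, idx, np.array([0.0, 1.0]), B) == 0.0
        assert evaluate_l2(A, idx, np.zeros(2), B) == pytest.approx(1.0)
        assert evaluate_l2(A, idx, np.array([1.0, 0.0]), B) == pytest.approx(math.sqrt(2))
        with pytest.raises(ValueError):
            evaluate_l2(A, np.array([], dtype=int), np.array([]), B)

    def test_cosine_cases(self):
        A = np.eye(2)
        idx = np.array([0, 1])
        assert evaluate_cos(A, idx, np.array([2.0, 2.0]), np.array([1.0, 1.0])) == pytest.approx(1.0)
        assert evaluate_cos(A, idx, np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.0
        assert evaluate_cos(A, idx, np.array([1.0, 1.0]), np.array([1.0, 0.0])) == pytest.approx(1 / math.sqrt(2))
        assert evaluate_cos(A, idx, np.zeros(2), np.array([1.0, 0.0])) == 0.0


class TestWeights:
    def test_single_iteration(self):
        assert probability_weights([2.0], [0.5]) == pytest.approx([1.0])

    def test_symmetry(self):
        assert probability_weights([1.0, 1.0], [0.5, 0.5]) == pytest.approx([0.5, 0.5])

    def test_hand_evaluated(self):
        w = probability_weights([1.0, 3.0], [0.9, 0.3])
        assert w == pytest.approx([0.75, 0.25])

    def test_all_zero_cosine_uniform_fallback(self):
        w = probability_weights([1.0, 2.0], [0.0, 0.0])
        p_l2 = np.array([2 / 3, 1 / 3])
        assert w == pytest.approx((p_l2 + 0.5) / 2)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(1e-6, 1e3), min_size=1, max_size=20),
        st.data(),
    )
    def test_weights_are_probability_vector(self, e_l2, data):
        e_cos = data.draw(
            st.lists(st.floats(0, 1), min_size=len(e_l2), max_size=len(e_l2))
        )
        w = probability_weights(e_l2, e_cos)
        assert np.all(w >= 0)
        assert np.sum(w) == pytest.approx(1.0)

    def test_normalization_and_clamp(self):
        assert probabilistic_distribution([2.0, 2.0, 4.0]) == pytest.approx([0.25, 0.25, 0.5])
        assert probabilistic_distribution([5.0]) == pytest.approx([1.0])
        assert probabilistic_distribution([-1.0, 2.0]) == pytest.approx([0.0, 1.0])
        with pytest.raises(ValueError):
            probabilistic_distribution([-1.0, 0.0])


class TestROI:
    def test_center_hand_sums(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert roi_center(coords, [0.5, 0.5]) == pytest.approx([1.0, 0, 0])
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 2.0, 0]])
        assert roi_center(coords, [0.25, 0.5, 0.25]) == pytest.approx([0.5, 0.5, 0])
        assert roi_center(np.array([[3.0, 1, 2]]), [1.0]) == pytest.approx([3, 1, 2])

    def test_covariance_hand_value(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        M = roi_covariance(coords, [0.5, 0.5], np.array([1.0, 0, 0]))
        assert M[0, 0] == pytest.approx(2.0)
        assert np.abs(M).sum() == pytest.approx(2.0)

    def test_covariance_degenerate_and_psd(self):
        assert np.array_equal(
            roi_covariance(np.array([[1.0, 2, 3]]), [1.0], np.array([1.0, 2, 3])),
            np.zeros((3, 3)),
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            coords = rng.normal(size=(15, 3))
            xp = rng.random(15)
            xp /= xp.sum()
            M = roi_covariance(coords, xp, roi_center(coords, xp))
            assert np.linalg.eigvalsh(M).min() >= -1e-12

    def test_box_from_diagonal_covariance(self):
        box = roi_box(np.diag([2.0, 0.5, 1.0]), np.zeros(3), 1.0, floor=0.1)
        # eigh returns ascending order; match axes by half-length
        got = dict(zip(box.half_lengths, [tuple(np.abs(a)) for a in box.axes.T]))
        assert set(np.round(box.half_lengths, 12)) == {2.0, 0.5, 1.0}
        for hl, ax in got.items():
            assert max(ax) == pytest.approx(1.0)

    def test_box_size_doubles_and_floor(self):
        b1 = roi_box(np.diag([2.0, 0.5, 1.0]), np.zeros(3), 1.0, floor=1e-9)
        b2 = roi_box(np.diag([2.0, 0.5, 1.0]), np.zeros(3), 2.0, floor=1e-9)
        assert sorted(b2.half_lengths) == pytest.approx([2 * h for h in sorted(b1.half_lengths)])
        b0 = roi_box(np.zeros((3, 3)), np.zeros(3), 1.0, floor=1.5)
        assert b0.half_lengths == pytest.approx([1.5, 1.5, 1.5])
        with pytest.raises(ValueError):
            roi_box(np.array([[0, 1, 0], [0, 0, 0], [0, 0, 0.0]]), np.zeros(3), 1.0, 0.1)

    def test_nodes_in_box_simple_and_rotated(self):
        nodes = np.array([[0.0, 0, 0], [5.0, 5, 5]])
        box = ROIBox(np.zeros(3), np.eye(3), np.array([1.0, 1, 1]))
        assert np.array_equal(nodes_in_box(nodes, box), [0])
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]]
        )
        box = ROIBox(np.array([1.0, 1, 1]), R, np.array([2.0, 0.5, 0.5]))
        inside_pt = box.center + 0.9 * box.half_lengths[0] * box.axes[:, 0]
        assert 0 in nodes_in_box(np.array([inside_pt]), box)

    def test_nodes_in_box_matches_brute_force(self):
        rng = np.random.default_rng(1)
        nodes = rng.uniform(-3, 3, size=(500, 3))
        for _ in range(100):
            center = rng.uniform(-1, 1, size=3)
            Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            half = rng.uniform(0.2, 2.0, size=3)
            box = ROIBox(center, Q, half)
            got = set(nodes_in_box(nodes, box).tolist())
            rel = (nodes - center) @ Q
            expect = set(np.flatnonzero(np.all(np.abs(rel) <= half + 1e-12, axis=1)).tolist())
            assert got == expect

    def test_nodes_sorted_by_distance(self):
        nodes = np.array([[0.9, 0, 0], [0.1, 0, 0], [-0.5, 0, 0]])
        box = ROIBox(np.zeros(3), np.eye(3), np.ones(3))
        assert np.array_equal(nodes_in_box(nodes, box), [1, 2, 0])


class TestSchedule:
    @pytest.mark.parametrize(
        "cut,expected",
        [(4, 1.0), (4 * 2**49, 2.0), (12831, 1.1791)],
    )
    def test_attenuation_values(self, cut, expected):
        assert attenuation_coefficient(cut, 4, 50) == pytest.approx(expected, abs=1e-4)

    def test_attenuation_below_floor(self):
        assert attenuation_coefficient(2, 4, 50) == 1.0

    def test_update_size_rules(self):
        beta, cut = 1.2, 144  # cut / beta^2 = 100 exactly
        assert update_size(100, cut, beta) == 1.0  # q = 1, boundary inclusive
        assert update_size(300, cut, beta) == 2.0  # q = 3 > 2
        assert update_size(40, cut, beta) == 0.5  # q = 0.4 < 1

    def test_refresh_index_hand_trace(self):
        x = np.array([6.0, 5, 4, 3, 2, 1])
        new_idx, new_cut = refresh_index(
            x, np.arange(6), np.array([3, 4]), cut_num=6, beta=2.0
        )
        assert new_cut == 3
        assert np.array_equal(new_idx, [3, 4, 0])

    def test_refresh_empty_roi_falls_back_to_energy(self):
        x = np.array([1.0, 9.0, 5.0, 7.0])
        new_idx, new_cut = refresh_index(x, np.arange(4), np.array([], dtype=int), 4, 2.0)
        assert new_cut == 2
        assert np.array_equal(new_idx, [1, 3])

    def test_refresh_beta_one_keeps_budget(self):
        x = np.array([2.0, 1.0])
        _, new_cut = refresh_index(x, np.arange(2), np.array([0]), 2, 1.0)
        assert new_cut == 2


class TestPostProcessing:
    def test_filter_all_identical_retained(self):
        assert np.array_equal(gaussian_filter_iterations([1.0] * 5, [0.9] * 5), np.arange(5))

    def test_filter_excludes_outlier(self):
        e_l2 = np.array([1.0, 1, 1, 10])
        retained = gaussian_filter_iterations(e_l2, [0.5] * 4)
        assert np.array_equal(retained, [0, 1, 2])
        assert abs(10 - e_l2.mean()) > e_l2.std()

    def test_filter_single_iteration(self):
        assert np.array_equal(gaussian_filter_iterations([2.0], [0.5]), [0])

    def _rec(self, idx, x, e_l2=1.0, e_cos=0.9):
        return IterationRecord(1, np.asarray(idx), np.asarray(x, dtype=float), e_l2, e_cos)

    def test_fusion_single_and_symmetric(self):
        r1 = self._rec([0, 1], [3.0, 1.0])
        x = final_distribution([r1], np.array([0]), 4)
        assert x == pytest.approx([0.75, 0.25, 0, 0])
        r2 = self._rec([2, 3], [1.0, 1.0])
        x = final_distribution([r1, r2], np.array([0, 1]), 4)
        assert x == pytest.approx([0.375, 0.125, 0.25, 0.25])
        assert x.sum() == pytest.approx(1.0)

    def test_fusion_unequal_scores_weighting(self):
        r1 = self._rec([0], [1.0], e_l2=1.0, e_cos=0.9)
        r2 = self._rec([1], [1.0], e_l2=3.0, e_cos=0.3)
        x = final_distribution([r1, r2], np.array([0, 1]), 2)
        assert x == pytest.approx([0.75, 0.25])


class TestFullLoop:
    @pytest.fixture(scope="class")
    def tiny_case(self, small_mesh, small_system):
        x_true = np.zeros(small_system.A.shape[1])
        x_true[len(x_true) // 2] = 1.0
        B = small_system.A @ x_true
        return small_mesh, small_system, x_true, B

    def test_noiseless_single_node_omp_exact(self, tiny_case):
        mesh, system, x_true, B = tiny_case
        res = run_peddrs(system, B, mesh, SolverSpec("omp", k=1))
        true_node = system.col_nodes[np.argmax(x_true)]
        assert res.x_final.argmax() == true_node
        assert res.x_final[true_node] == pytest.approx(1.0)

    def test_cut_num_trace_matches_ceil_schedule(self, tiny_case):
        mesh, system, x_true, B = tiny_case
        res = run_peddrs(system, B, mesh, SolverSpec("tikhonov"))
        c0 = res.records[0].cut_num
        beta = attenuation_coefficient(c0)
        expect = [c0]
        for _ in res.records[1:]:
            expect.append(math.ceil(expect[-1] / beta))
        assert [r.cut_num for r in res.records] == expect

    def test_terminates_within_l_max_and_weights_normalized(self, tiny_case):
        mesh, system, x_true, B = tiny_case
        res = run_peddrs(system, B, mesh, SolverSpec("dsvd"))
        assert len(res.records) <= 50
        w = np.array([r.weight for r in res.records])
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w >= 0)
        assert np.all(res.x_final >= 0)
        assert res.x_final.sum() == pytest.approx(1.0)

    def test_support_sizes_non_increasing(self, tiny_case):
        mesh, system, x_true, B = tiny_case
        res = run_peddrs(system, B, mesh, SolverSpec("tikhonov"))
        cuts = [r.cut_num for r in res.records]
        assert all(a >= b for a, b in zip(cuts, cuts[1:]))
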