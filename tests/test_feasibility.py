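"""Hyperslab constraints, half-space projections, and the AMS sweep."""

import numpy as np
import pytest

import superplan as spn

from conftest import feasible_toy, toy_constraints


def reference_sweep(x, A, C, lam, order, weight_scale=1.0):
    """Straight-line re-implementation of the sweep via halfspace_step."""
    x = np.asarray(x, dtype=float).copy()
    dense = A.csr.toarray()
    for i in order:
        w = lam * weight_scale * C.weights[i]
        x = spn.halfspace_step(x, dense[i], C.upper[i], "upper", w)
        x = spn.halfspace_step(x, dense[i], C.lower[i], "lower", w)
    return np.maximum(x, 0.0)


class TestHalfspaceStep:
    def test_exact_projection_closes_residual(self):
        x = spn.halfspace_step([1.0, 1.0], np.array([3.0, 4.0]), 2.0,
                               "upper", 1.0)
        np.testing.assert_allclose(x, [0.4, 0.2])
        assert np.dot([3.0, 4.0], x) == pytest.approx(2.0)

    def test_under_relaxation_halves_residual(self):
        x = spn.halfspace_step([1.0, 1.0], np.array([3.0, 4.0]), 2.0,
                               "upper", 0.5)
        assert np.dot([3.0, 4.0], x) == pytest.approx(4.5)

    def test_satisfied_constraint_is_noop(self):
        x0 = np.array([1.0, 1.0])
        x = spn.halfspace_step(x0, np.array([1.0, 0.0]), 5.0, "upper", 1.0)
        np.testing.assert_array_equal(x, x0)
        x = spn.halfspace_step(x0, np.array([1.0, 0.0]), 0.5, "lower", 1.0)
        np.testing.assert_array_equal(x, x0)

    def test_zero_row_skipped(self):
        x = spn.halfspace_step([1.0], np.array([0.0]), -1.0, "upper", 1.0)
        np.testing.assert_array_equal(x, [1.0])

    def test_random_violated_halfspaces_projected_exactly(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 8))
            a = rng.uniform(-2, 2, m)
            if not a.any():
                continue
            x = rng.uniform(-5, 5, m)
            u = float(a @ x) - rng.uniform(0.1, 10)  # force violation
            xp = spn.halfspace_step(x, a, u, "upper", 1.0)
            assert abs(a @ xp - u) <= 1e-9 * max(1.0, abs(u))


class TestPrescriptionToConstraints:
    def test_phantom_prescription_bounds_and_weights(self, phantom_structures,
                                                     default_grid):
        pres = spn.default_phantom_prescription()
        C = spn.prescription_to_constraints(phantom_structures, pres)
        sets = phantom_structures.exclusive_partition(default_grid.n)
        t, c, b = sets["Target"], sets["Core"], sets["Body"]
        assert np.all(C.lower[t] == 59.0) and np.all(C.upper[t] == 61.0)
        assert np.all(C.lower[c] == 0.0) and np.all(C.upper[c] == 20.0)
        assert np.all(C.upper[b] == 30.0)
        assert np.all(C.weights[t] == 1.0)
        assert np.all(C.weights[c] == pytest.approx(0.1))
        assert np.all(C.weights[b] == pytest.approx(0.03))

    def test_trivial_slab_gives_empty_active_set(self):
        ss = spn.StructureSet([spn.Structure("All", np.arange(4), 0)])
        C = spn.prescription_to_constraints(
            ss, [spn.VOIPrescription("All", 0.0, np.inf, 1.0)])
        assert C.n_active == 0

    def test_priority_shields_nested_structure(self):
        ss = spn.StructureSet([
            spn.Structure("Target", [1, 2], 0),
            spn.Structure("Body", [0, 1, 2, 3], 2),
        ])
        C = spn.prescription_to_constraints(ss, [
            spn.VOIPrescription("Target", 59, 61, 1000),
            spn.VOIPrescription("Body", 0, 30, 30),
        ])
        assert C.upper[1] == 61.0 and C.upper[2] == 61.0  # not Body's 30
        assert C.upper[0] == 30.0 and C.upper[3] == 30.0

    def test_inconsistent_bounds_rejected(self):
        with pytest.raises(ValueError):
            spn.VOIPrescription("Target", 61.0, 59.0, 1.0)


class TestControlSequences:
    def _system(self, weights):
        n = len(weights)
        lower = np.zeros(n)
        upper = np.ones(n)  # all active
        return spn.ConstraintSystem.from_bounds(lower, upper, weights)

    def test_cyclic_is_sorted_active_set(self):
        C = self._system([0.5, 0.5, 0.5])
        C.active = np.array([2, 0, 1])
        np.testing.assert_array_equal(
            spn.make_control_sequence("cyclic", C), [0, 1, 2])

    def test_weight_descending_example(self):
        C = self._system([0.1, 0.9, 0.5])
        np.testing.assert_array_equal(
            spn.make_control_sequence("weight_descending", C), [1, 2, 0])
        np.testing.assert_array_equal(
            spn.make_control_sequence("weight_ascending", C), [0, 2, 1])

    def test_random_is_seed_deterministic(self):
        C = self._system([1.0] * 8)
        a = spn.make_control_sequence("random", C, np.random.default_rng(7))
        b = spn.make_control_sequence("random", C, np.random.default_rng(7))
        c = spn.make_control_sequence("random", C, np.random.default_rng(8))
        np.testing.assert_array_equal(a, b)
        assert sorted(c.tolist()) == sorted(a.tolist())

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            spn.make_control_sequence("zigzag", self._system([1.0]))

    def test_control_sequence_redraws_each_sweep(self):
        C = self._system([1.0] * 30)
        seq = spn.ControlSequence("random", seed=0)
        draws = {tuple(seq.draw(C)) for _ in range(3)}
        assert len(draws) > 1  # redrawn, not frozen


class TestAmsSweep:
    def test_decoupled_identity_system_feasible_after_one_sweep(self):
        A = spn.DoseInfluenceMatrix(np.eye(2))
        C = spn.ConstraintSystem.from_bounds([1.0, 0.0], [2.0, 1.0])
        x = spn.ams_sweep(np.array([0.0, 3.0]), A, C, lam=1.0)
        np.testing.assert_allclose(x, [1.0, 1.0])

    def test_orthant_clamp_after_projection(self):
        # projecting onto <[2,1], x> <= 0 from [1,1] lands at [-0.2, 0.4];
        # the post-sweep orthant projection clamps the negative component
        A = spn.DoseInfluenceMatrix([[2.0, 1.0]])
        C = spn.ConstraintSystem.from_bounds([0.0], [0.0])
        x = spn.ams_sweep(np.array([1.0, 1.0]), A, C, lam=1.0)
        np.testing.assert_allclose(x, [0.0, 0.4])

    def test_matches_reference_implementation(self, rng):
        for _ in range(10):
            toy = spn.make_toy_problem(n=10, m=4, density=0.5, seed=int(rng.integers(1e6)))
            C = toy_constraints(toy)
            x0 = rng.uniform(0, 3, 4)
            order = spn.make_control_sequence("cyclic", C)
            fast = spn.ams_sweep(x0, toy.matrix, C, 1.0, order)
            slow = reference_sweep(x0, toy.matrix, C, 1.0, order)
            np.testing.assert_allclose(fast, slow, rtol=1e-12, atol=1e-12)

    def test_pure_function_of_inputs(self):
        toy = feasible_toy(0)
        C = toy_constraints(toy)
        x0 = np.full(30, 2.0)
        a = spn.ams_sweep(x0, toy.matrix, C)
        b = spn.ams_sweep(x0, toy.matrix, C)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(x0, np.full(30, 2.0))  # untouched

    def test_invalid_relaxation_rejected(self):
        toy = feasible_toy(0)
        with pytest.raises(ValueError):
            spn.ams_sweep(np.zeros(30), toy.matrix, toy_constraints(toy), lam=2.5)

    def test_fejer_monotone_toward_witness(self):
        toy = feasible_toy(4)
        C = toy_constraints(toy)
        x = np.zeros(30)
        dist = np.linalg.norm(x - toy.witness)
        for _ in range(30):
            x = spn.ams_sweep(x, toy.matrix, C, lam=1.5)
            new = np.linalg.norm(x - toy.witness)
            assert new <= dist + 1e-10
            dist = new


class TestProximityMeasures:
    def test_single_voxel_example(self):
        A = spn.DoseInfluenceMatrix([[2.0]])
        C = spn.ConstraintSystem.from_bounds([0.0], [4.0])
        assert spn.proximity_V([3.0], A, C) == pytest.approx(1.0)
        assert spn.max_violation([3.0], A, C) == pytest.approx(2.0)

    def test_zero_on_feasible_point(self):
        toy = feasible_toy(2)
        C = toy_constraints(toy)
        assert spn.proximity_V(toy.witness, toy.matrix, C) == 0.0
        assert spn.max_violation(toy.witness, toy.matrix, C) == 0.0

    def test_matches_per_voxel_loop(self, rng):
        toy = spn.make_toy_problem(n=25, m=6, density=0.5, seed=11)
        C = toy_constraints(toy)
        x = rng.uniform(0, 3, 6)
        dense = toy.matrix.csr.toarray()
        acc, mx = 0.0, 0.0
        for i in C.active:
            d = dense[i] @ x
            below = max(C.lower[i] - d, 0.0)
            above = max(d - C.upper[i], 0.0)
            acc += (below ** 2 + above ** 2) / (dense[i] @ dense[i])
            mx = max(mx, below, above)
        assert spn.proximity_V(x, toy.matrix, C) == pytest.approx(acc / C.n_active)
        assert spn.max_violation(x, toy.matrix, C) == pytest.approx(mx)


class TestFeasibilitySolve:
    def test_witness_start_stops_by_stagnation_at_zero(self):
        toy = feasible_toy(5)
        C = toy_constraints(toy)
        x, hist = spn.feasibility_solve(toy.witness, toy.matrix, C)
        assert hist.status == "stopped_criterion"
        assert hist.V[-1] == 0.0
        assert hist.iteration[-1] <= 10

    def test_infeasible_problem_plateaus_positive(self):
        toy = spn.make_toy_problem(n=50, m=10, density=0.3, feasible=False,
                                   slack=0.5, seed=3)
        C = toy_constraints(toy)
        x, hist = spn.feasibility_solve(np.zeros(10), toy.matrix, C,
                                        max_sweeps=400, tol_V=-1)
        V = np.array(hist.V)
        assert V[-1] > 1e-8  # strictly positive plateau
        tail = V[len(V) // 2:]
        # eventually non-increasing up to numerical dust near the plateau
        assert np.all(np.diff(tail) <= 1e-6 * max(1.0, V[-1]))
        # the relative-stagnation rule detects the plateau on its own
        _, hist2 = spn.feasibility_solve(np.zeros(10), toy.matrix, C,
                                         max_sweeps=400)
        assert hist2.status == "stopped_criterion" and hist2.V[-1] > 1e-8

    def test_negative_x0_rejected(self):
        toy = feasible_toy(0)
        with pytest.raises(ValueError):
            spn.feasibility_solve(-np.ones(30), toy.matrix, toy_constraints(toy))

    def test_history_csv_round_trip(self, tmp_path):
        toy = feasible_toy(6)
        C = toy_constraints(toy)
        _, hist = spn.feasibility_solve(np.zeros(30), toy.matrix, C,
                                        max_sweeps=20, tol_V=-1)
        hist.to_csv(tmp_path / "h.csv")
        back = spn.RunHistory.from_csv(tmp_path / "h.csv")
        np.testing.assert_array_equal(back.V, hist.V)
        np.testing.assert_array_equal(back.max_violation, hist.max_violation)
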