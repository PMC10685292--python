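"""Dose objectives, DVH quantile, gradients, and the composite chain rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import superplan as spn
from superplan.objectives import canonical_kind


def central_difference(fun, d, h_scale=1e-4):
    """Central finite-difference gradient of a dose-space objective."""
    d = np.asarray(d, dtype=float)
    g = np.zeros_like(d)
    for i in range(d.size):
        h = h_scale * max(1.0, abs(d[i]))
        dp, dm = d.copy(), d.copy()
        dp[i] += h
        dm[i] -= h
        g[i] = (fun(dp) - fun(dm)) / (2 * h)
    return g


def brute_force_quantile(d, volume):
    """Threshold scan: dose value minimizing |fraction(d >= t) - volume|.

    Candidate thresholds are the dose values themselves; ties are broken
    toward the larger covered fraction (more voxels), matching nearest rank.
    """
    d = np.asarray(d, dtype=float)
    best_t, best_err, best_frac = None, np.inf, -1.0
    for t in np.sort(np.unique(d))[::-1]:
        frac = np.mean(d >= t)
        err = abs(frac - volume)
        if err < best_err - 1e-15 or (abs(err - best_err) <= 1e-15
                                      and frac > best_frac):
            best_t, best_err, best_frac = t, err, frac
    return best_t


class TestObjectiveValues:
    @pytest.mark.parametrize("kind,d,d_ref,expected", [
        ("sq_deviation", [59, 60, 61], 60.0, 2.0 / 3.0),
        ("sq_overdose", [10, 25, 30], 20.0, 125.0 / 3.0),
        ("sq_underdose", [10, 25, 30], 20.0, 100.0 / 3.0),
        ("mean_dose", [0, 0, 0], None, 0.0),
        ("mean_dose", [1, 2, 3], None, 2.0),
        ("sq_deviation", [60, 60], 60.0, 0.0),
    ])
    def test_hand_computed_values(self, kind, d, d_ref, expected):
        assert spn.objective_value(kind, d, d_ref) == pytest.approx(expected)

    def test_paper_style_aliases_resolve(self):
        assert canonical_kind("f_sqdev") == "sq_deviation"
        assert canonical_kind("f_sqdev+") == "sq_overdose"
        assert canonical_kind("f_maxDVH") == "max_dvh"
        with pytest.raises(ValueError):
            canonical_kind("nonsense")

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            spn.objective_value("mean_dose", [])

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=20),
           st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_mean_dose_homogeneous(self, d, c):
        lhs = spn.objective_value("mean_dose", c * np.asarray(d))
        assert lhs == pytest.approx(c * spn.objective_value("mean_dose", d))

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_squared_objectives_nonnegative(self, d):
        for kind in ("sq_deviation", "sq_overdose", "sq_underdose"):
            assert spn.objective_value(kind, d, 50.0) >= 0.0


class TestGradients:
    def test_mean_dose_gradient_is_uniform(self):
        np.testing.assert_array_equal(
            spn.objective_gradient("mean_dose", [1, 2, 3, 4]),
            np.full(4, 0.25))

    def test_sq_deviation_zero_at_reference(self):
        g = spn.objective_gradient("sq_deviation", [60.0] * 5, 60.0)
        np.testing.assert_array_equal(g, np.zeros(5))

    @pytest.mark.parametrize("kind", ["sq_deviation", "sq_overdose",
                                      "sq_underdose", "mean_dose"])
    def test_matches_central_differences(self, kind, rng):
        for _ in range(5):
            d = np.round(rng.uniform(0, 100, size=12), 0)  # keep off kinks
            d += 0.3
            g = spn.objective_gradient(kind, d, 47.5)
            g_fd = central_difference(
                lambda dd: spn.objective_value(kind, dd, 47.5), d)
            np.testing.assert_allclose(g, g_fd, rtol=1e-5, atol=1e-8)

    @pytest.mark.parametrize("kind", ["max_dvh", "min_dvh"])
    def test_dvh_gradients_match_central_differences(self, kind, rng):
        for _ in range(5):
            # distinct integer doses + fractional reference keep every voxel
            # away from the selection boundary, where the objective is smooth
            d = rng.choice(np.arange(0, 200), size=15, replace=False) + 0.25
            g = spn.objective_gradient(kind, d, 99.75, volume=0.3)
            g_fd = central_difference(
                lambda dd: spn.objective_value(kind, dd, 99.75, volume=0.3), d)
            np.testing.assert_allclose(g, g_fd, rtol=1e-5, atol=1e-8)


class TestDVHQuantile:
    @pytest.mark.parametrize("d,v,expected", [
        ([10, 20, 30, 40], 0.25, 40.0),
        ([10, 20, 30, 40], 0.5, 30.0),
        ([7, 7, 7], 0.1, 7.0),
        ([7, 7, 7], 0.9, 7.0),
    ])
    def test_nearest_rank_examples(self, d, v, expected):
        assert spn.inverse_dvh_quantile(d, v) == expected

    def test_agrees_with_threshold_scan(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 30))
            d = rng.uniform(0, 80, size=n)
            v = float(rng.uniform(0.05, 0.95))
            assert spn.inverse_dvh_quantile(d, v) == brute_force_quantile(d, v)

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            spn.inverse_dvh_quantile([1.0], 0.0)
        with pytest.raises(ValueError):
            spn.inverse_dvh_quantile([1.0], 1.0)


class TestDVHObjectives:
    def test_no_violators_gives_zero(self):
        value, grad = spn.dvh_objective("max_dvh", [10, 20, 30], 40.0, 0.5)
        assert value == 0.0
        np.testing.assert_array_equal(grad, np.zeros(3))

    def test_stated_selection_rule(self):
        # d_V = 70 (hottest third), penalized voxels {55, 70}
        value, grad = spn.dvh_objective("max_dvh", [40, 55, 70], 50.0, 1 / 3)
        assert value == pytest.approx((25.0 + 400.0) / 3.0)
        assert grad[0] == 0.0 and grad[1] > 0 and grad[2] > 0

    def test_min_dvh_mirrors_max_dvh_under_reflection(self, rng):
        """With odd |S| and V=1/2 the quantile rank is self-mirroring, so
        min_dvh(d; d_ref) equals max_dvh(-d; -d_ref) exactly."""
        for _ in range(20):
            d = rng.choice(np.arange(1, 100), size=9, replace=False).astype(float)
            d_ref = 50.5
            v_min, _ = spn.dvh_objective("min_dvh", d, d_ref, 0.5)
            v_max, _ = spn.dvh_objective("max_dvh", -d, -d_ref, 0.5)
            assert v_min == pytest.approx(v_max)

    def test_gradient_zero_off_penalized_set(self):
        d = np.array([10.0, 45.0, 60.0, 90.0])
        _, grad = spn.dvh_objective("max_dvh", d, 50.0, 0.5)
        # d_V = 60; penalized set {60}; 90 is above the quantile, 45 below ref
        assert grad[0] == grad[1] == grad[3] == 0.0 and grad[2] > 0


class TestObjectiveSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            spn.ObjectiveSpec("sq_deviation", "Target", weight=-1, d_ref=60)
        with pytest.raises(ValueError):
            spn.ObjectiveSpec("sq_deviation", "Target", weight=1)  # no d_ref
        with pytest.raises(ValueError):
            spn.ObjectiveSpec("max_dvh", "Target", weight=1, d_ref=50)  # no V
        spec = spn.ObjectiveSpec("f_sqdev", "Target", 1000.0, 60.0)
        assert spec.kind == "sq_deviation"


class TestCompositeObjective:
    def _structures(self, n):
        return spn.StructureSet([spn.Structure("All", np.arange(n), 0)])

    def test_identity_mean_dose_gradient(self):
        n = 6
        obj = spn.CompositeObjective(
            [spn.ObjectiveSpec("mean_dose", "All", 1.0)],
            self._structures(n), spn.DoseInfluenceMatrix(np.eye(n)))
        f, g = obj.value_and_gradient(np.ones(n))
        assert f == pytest.approx(1.0)
        np.testing.assert_allclose(g, np.full(n, 1.0 / n))

    def test_zero_weights_give_zero(self, rng):
        n = 5
        obj = spn.CompositeObjective(
            [spn.ObjectiveSpec("sq_deviation", "All", 0.0, 10.0)],
            self._structures(n), spn.DoseInfluenceMatrix(np.eye(n)))
        f, g = obj.value_and_gradient(rng.uniform(0, 5, n))
        assert f == 0.0
        np.testing.assert_array_equal(g, np.zeros(n))

    def test_additive_in_specs(self, rng, phantom_problem):
        ss, A = phantom_problem.structures, phantom_problem.matrix
        s1 = [spn.ObjectiveSpec("sq_deviation", "Target", 10.0, 60.0)]
        s2 = [spn.ObjectiveSpec("sq_overdose", "Core", 3.0, 20.0)]
        x = rng.uniform(0, 50, A.m)
        f1 = spn.CompositeObjective(s1, ss, A).value(x)
        f2 = spn.CompositeObjective(s2, ss, A).value(x)
        f12 = spn.CompositeObjective(s1 + s2, ss, A).value(x)
        assert f12 == pytest.approx(f1 + f2)

    def test_chain_rule_matches_finite_differences(self, rng):
        n, m = 12, 5
        A = spn.DoseInfluenceMatrix(rng.uniform(0, 1, (n, m)))
        ss = spn.StructureSet([
            spn.Structure("A", np.arange(0, 6), 0),
            spn.Structure("B", np.arange(6, 12), 1),
        ])
        specs = [spn.ObjectiveSpec("sq_deviation", "A", 2.0, 3.0),
                 spn.ObjectiveSpec("sq_overdose", "B", 1.5, 1.0),
                 spn.ObjectiveSpec("mean_dose", "B", 0.5)]
        obj = spn.CompositeObjective(specs, ss, A)
        x = rng.uniform(0, 5, m)
        _, g = obj.value_and_gradient(x)
        g_fd = np.zeros(m)
        for j in range(m):
            h = 1e-4 * max(1.0, abs(x[j]))
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            g_fd[j] = (obj.value(xp) - obj.value(xm)) / (2 * h)
        np.testing.assert_allclose(g, g_fd, rtol=1e-5, atol=1e-8)

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError):
            spn.CompositeObjective(
                [spn.ObjectiveSpec("mean_dose", "Nope", 1.0)],
                self._structures(3), spn.DoseInfluenceMatrix(np.eye(3)))
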