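import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emgdose as e
from emgdose.dosage import objective_gradient


def profile(s, d=None):
    s = np.asarray(s, dtype=float)
    d = np.zeros_like(s) if d is None else np.asarray(d, dtype=float)
    return e.ActivationProfile(s=s, d=d)


W_SUP = e.AllocationWeights(1.0, 0.0)


class TestActivationProfile:
    @staticmethod
    def _pred_frame(values):
        rows = []
        for code in range(4):
            for _ in range(3):
                rows.append({"movement_code": code,
                             **{m: values(m, code) for m in e.MUSCLES}})
        return pd.DataFrame(rows)

    def test_constant_field(self):
        preds = self._pred_frame(lambda m, c: 0.5)
        prof = e.activation_profile(preds)
        np.testing.assert_allclose(prof.s, 0.5)
        np.testing.assert_allclose(prof.d, 0.5)

    def test_layer_separation(self):
        preds = self._pred_frame(
            lambda m, c: 1.0 if e.LAYER_MAP[m] == "superficial" else 0.0
        )
        prof = e.activation_profile(preds)
        np.testing.assert_allclose(prof.s, 1.0)
        np.testing.assert_allclose(prof.d, 0.0)

    def test_empty_movement_cell_is_error(self):
        preds = self._pred_frame(lambda m, c: 0.5)
        preds = preds[preds["movement_code"] != 2]
        with pytest.raises(ValueError, match="external rotation at side"):
            e.activation_profile(preds)

    def test_planted_scaption_dominance(self, feature_table):
        """Scaption activates all three superficial-or-deep-heavy gains, so
        its predicted superficial mean must rank highest."""
        report = e.run_comparison(feature_table, [e.ModelSpec("xgboost", seed=0)])
        preds = report.predictions["xgboost"].copy()
        preds["movement_code"] = feature_table["movement_code"]
        prof = e.activation_profile(preds)
        assert np.argmax(prof.d) == 0  # scaption activates all deep muscles
        assert prof.s[0] > prof.s[2]  # and more superficial drive than ext. rot.

    def test_out_of_range_profile_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            profile([1.5, 0, 0, 0])


class TestObjective:
    def test_all_zero_profile(self):
        assert e.objective([15, 15, 15, 15], profile([0, 0, 0, 0]), W_SUP) == 0.0

    def test_uniform_activation(self):
        prof = profile([1, 1, 1, 1])
        assert e.objective([15, 15, 15, 15], prof, W_SUP) == pytest.approx(-60.0)

    def test_variance_penalty_hand_value(self):
        prof = profile([1, 1, 1, 1])
        # Var((30,10,10,10)) = (15² + 3·5²)/4 = 75
        assert e.objective([30, 10, 10, 10], prof, W_SUP) == pytest.approx(
            -60.0 + 0.1 * 75
        )

    def test_literal_mode_flips_variance_sign(self):
        prof = profile([1, 1, 1, 1])
        goal = e.objective([30, 10, 10, 10], prof, W_SUP, sign_mode="goal-consistent")
        literal = e.objective([30, 10, 10, 10], prof, W_SUP, sign_mode="literal")
        assert literal == pytest.approx(-60.0 - 7.5)
        assert goal - literal == pytest.approx(2 * 0.1 * 75)

    def test_wrong_dimension(self):
        with pytest.raises(ValueError, match="entries"):
            e.objective([15, 15], profile([0, 0, 0, 0]), W_SUP)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        prof = profile(rng.uniform(0, 1, 4), rng.uniform(0, 1, 4))
        w = e.AllocationWeights(0.7, 0.3)
        x = rng.uniform(5, 30, 4)
        grad = objective_gradient(x, prof, w)
        h = 1e-6
        for i in range(4):
            dx = np.zeros(4)
            dx[i] = h
            fd = (e.objective(x + dx, prof, w) - e.objective(x - dx, prof, w)) / (2 * h)
            assert grad[i] == pytest.approx(fd, abs=1e-6)


class TestSolveAllocation:
    def test_symmetric_profile_equal_split(self):
        plan = e.solve_allocation(profile([0.5] * 4, [0.5] * 4),
                                  e.AllocationWeights(0.7, 0.3))
        np.testing.assert_allclose(plan.x, 15.0, atol=0.01)

    def test_single_dominant_closed_form(self):
        plan = e.solve_allocation(profile([1, 0, 0, 0]), W_SUP)
        np.testing.assert_allclose(plan.x, [30, 10, 10, 10], atol=0.1)
        assert plan.objective_value == pytest.approx(-22.5, abs=1e-3)

    def test_huge_variance_penalty_forces_equal_split(self):
        constraints = e.AllocationConstraints(variance_penalty=1e3)
        plan = e.solve_allocation(profile([1, 0, 0, 0]), W_SUP, constraints)
        np.testing.assert_allclose(plan.x, 15.0, atol=0.1)

    def test_feasibility_invariants(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            prof = profile(rng.uniform(0, 1, 4), rng.uniform(0, 1, 4))
            plan = e.solve_allocation(prof, e.AllocationWeights(0.3, 0.7))
            assert plan.x.sum() == pytest.approx(60.0, abs=1e-6)
            assert (plan.x >= 5 - 1e-9).all() and (plan.x <= 30 + 1e-9).all()

    def test_never_worse_than_equal_split(self):
        rng = np.random.default_rng(11)
        prof = profile(rng.uniform(0, 1, 4), rng.uniform(0, 1, 4))
        w = e.AllocationWeights(0.5, 0.5)
        plan = e.solve_allocation(prof, w)
        assert plan.objective_value <= e.objective([15] * 4, prof, w) + 1e-12

    def test_initialization_independence(self):
        """The goal-consistent objective is convex, so 10 random feasible
        starts must land on the equal-split solution within 0.1 min."""
        rng = np.random.default_rng(21)
        prof = profile(rng.uniform(0, 1, 4), rng.uniform(0, 1, 4))
        w = e.AllocationWeights(0.7, 0.3)
        reference = e.solve_allocation(prof, w)
        for _ in range(10):
            perturb = rng.uniform(-5.0, 5.0, 4)
            x0 = 15.0 + perturb - perturb.mean()  # feasible: sum 60, within bounds
            plan = e.solve_allocation(prof, w, x0=x0)
            np.testing.assert_allclose(plan.x, reference.x, atol=0.1)

    def test_infeasible_constraints_rejected_before_solving(self):
        with pytest.raises(ValueError, match="infeasible"):
            e.AllocationConstraints(total_minutes=10.0)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.permutations([0, 1, 2, 3]))
    def test_permutation_symmetry(self, perm):
        s = np.array([0.9, 0.2, 0.5, 0.1])
        d = np.array([0.3, 0.8, 0.1, 0.4])
        w = e.AllocationWeights(0.7, 0.3)
        base = e.solve_allocation(profile(s, d), w)
        perm = np.array(perm)
        permuted = e.solve_allocation(profile(s[perm], d[perm]), w)
        np.testing.assert_allclose(permuted.x, base.x[perm], atol=0.01)


class TestGridOracle:
    def test_dominant_case_lattice_optimum(self):
        plan = e.grid_oracle(profile([1, 0, 0, 0]), W_SUP, resolution=0.5)
        np.testing.assert_allclose(plan.x, [30, 10, 10, 10])

    def test_symmetric_profile_equal_split(self):
        plan = e.grid_oracle(profile([0.4] * 4, [0.4] * 4),
                             e.AllocationWeights(0.5, 0.5))
        np.testing.assert_allclose(plan.x, 15.0)

    def test_oracle_agreement_on_random_profiles(self):
        """The solver is never worse than the exhaustive 0.5-min lattice, and
        the lattice best is within the resolution-limited quadratic gap."""
        rng = np.random.default_rng(2)
        weights = [e.AllocationWeights(*w) for w in ((0.7, 0.3), (0.5, 0.5), (0.3, 0.7))]
        for i in range(50):
            prof = profile(rng.uniform(0, 1, 4), rng.uniform(0, 1, 4))
            w = weights[i % 3]
            solved = e.solve_allocation(prof, w)
            oracle = e.grid_oracle(prof, w, resolution=0.5)
            assert solved.objective_value <= oracle.objective_value + 1e-3
            assert oracle.objective_value - solved.objective_value <= 0.05
            assert np.abs(solved.x - oracle.x).max() <= 0.5 + 1e-6

    def test_monotone_response_interior(self):
        """Raising one exercise's superficial activation never lowers its
        allocated time while the solution stays interior."""
        base_s = np.array([0.50, 0.48, 0.52, 0.49])
        d = np.full(4, 0.5)
        w = e.AllocationWeights(0.7, 0.3)
        times = []
        for bump in (0.0, 0.05, 0.10):
            s = base_s.copy()
            s[1] += bump
            plan = e.solve_allocation(profile(s, d), w)
            assert (plan.x > 5.1).all() and (plan.x < 29.9).all()
            times.append(plan.x[1])
        assert times[0] <= times[1] <= times[2]

    def test_empty_lattice_is_error(self):
        constraints = e.AllocationConstraints(total_minutes=61.7)
        with pytest.raises(ValueError, match="lattice"):
            e.grid_oracle(profile([1, 0, 0, 0]), W_SUP, constraints, resolution=2.0)


class TestRunCases:
    def test_three_plans_sum_to_total(self):
        rng = np.random.default_rng(4)
        prof = profile(rng.uniform(0, 1, 4), rng.uniform(0, 1, 4))
        plans = e.run_cases(prof)
        assert [p.weights.case_label for p in plans] == ["70/30", "50/50", "30/70"]
        for plan in plans:
            assert plan.x.sum() == pytest.approx(60.0, abs=1e-6)

    def test_equal_layer_profiles_case_invariant(self):
        """With s = d, the combined coefficient ws·s + wd·d equals s for every
        named case (ws + wd = 1), so all cases yield the identical plan."""
        prof = profile([0.8, 0.3, 0.5, 0.4], [0.8, 0.3, 0.5, 0.4])
        plans = e.run_cases(prof)
        for plan in plans[1:]:
            np.testing.assert_allclose(plan.x, plans[0].x, atol=0.01)

    def test_dominant_exercise_takes_maximum_in_all_cases(self):
        prof = profile([1.0, 0.0, 0.05, 0.0], [0.95, 0.05, 0.0, 0.0])
        plans = e.run_cases(prof)
        for plan in plans:
            assert np.argmax(plan.x) == 0
            assert plan.x[0] > max(plan.x[1:]) + 10  # clear separation

    def test_fully_dominant_exercise_hits_upper_bound(self):
        prof = profile([1.0, 0.0, 0.0, 0.0], [1.0, 0.0, 0.0, 0.0])
        for plan in e.run_cases(prof):
            assert plan.x[0] == pytest.approx(30.0, abs=0.1)
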