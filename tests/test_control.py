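import numpy as np
import pytest

from drinksmoke import (
    ControlPath,
    ObjectiveWeights,
    Trajectory,
    adjoint_rhs,
    control_update,
    efficacy,
    forward_backward_sweep,
    hamiltonian,
    objective,
    rhs_controlled,
    rhs_uncontrolled,
    simulate,
)
from drinksmoke.control import ControlBoundsError, jacobian_controlled


def random_point(rng, state_scale=3.0, adjoint_scale=50.0):
    state = rng.uniform(0.0, state_scale, size=7)
    controls = rng.uniform(0.0, 1.0, size=5)
    adjoints = rng.uniform(-adjoint_scale, adjoint_scale, size=7)
    return state, controls, adjoints


class TestControlledRhs:
    def test_zero_controls_reduce_to_uncontrolled(self, table2):
        rng = np.random.default_rng(0)
        for _ in range(10):
            state = rng.uniform(0.0, 5.0, size=7)
            d_ctrl = rhs_controlled(0.0, state, np.zeros(5), table2)
            d_free = rhs_uncontrolled(0.0, state, table2)
            assert np.max(np.abs(d_ctrl - d_free)) <= 1e-15

    def test_full_prevention_removes_uptake(self, table2):
        state = np.array([0.6, 0.2, 0.1, 0.06, 0.02, 0.0, 0.0])
        u = np.array([1.0, 1.0, 0.0, 0.3, 0.0])
        d = rhs_controlled(0.0, state, u, table2)
        p = table2
        # with u1 = u2 = 1 every force-driven inflow vanishes
        assert d[1] == pytest.approx(-(p.mu + p.phi1 + p.delta1 + 0.3) * state[1])
        assert d[3] == pytest.approx(-(p.mu + p.phi3 + p.k1) * state[3])

    def test_population_balance_with_controls(self, table2):
        rng = np.random.default_rng(1)
        state, u, _ = random_point(rng)
        d = rhs_controlled(0.0, state, u, table2)
        p = table2
        expected = (
            p.xi - p.mu * state.sum()
            - p.phi1 * state[1] - p.phi2 * state[2] - p.phi3 * state[3]
        )
        assert d.sum() == pytest.approx(expected, abs=1e-12)

    def test_out_of_bounds_controls_rejected(self, table2):
        with pytest.raises(ControlBoundsError):
            rhs_controlled(0.0, np.ones(7), np.array([0.5, 1.2, 0, 0, 0]), table2)

    def test_jacobian_matches_finite_differences(self, table2):
        rng = np.random.default_rng(2)
        state, u, _ = random_point(rng)
        J = jacobian_controlled(state, u, table2)
        fd = np.empty((7, 7))
        for j in range(7):
            h = 1e-6 * max(1.0, abs(state[j]))
            hi, lo = state.copy(), state.copy()
            hi[j] += h
            lo[j] -= h
            fd[:, j] = (
                rhs_controlled(0, hi, u, table2) - rhs_controlled(0, lo, u, table2)
            ) / (2 * h)
        np.testing.assert_allclose(J, fd, atol=1e-6)


class TestObjective:
    def test_zero_everything(self):
        times = np.linspace(0, 52, 53)
        traj = Trajectory(times=times, states=np.zeros((53, 7)))
        assert objective(traj, ControlPath.zeros(times), ObjectiveWeights()) == 0.0

    def test_constant_drinker_rectangle(self):
        times = np.linspace(0, 52, 5201)
        states = np.zeros((5201, 7))
        states[:, 1] = 1.0
        traj = Trajectory(times=times, states=states)
        J = objective(traj, ControlPath.zeros(times), ObjectiveWeights(A1=100))
        assert J == pytest.approx(5200.0, rel=1e-12)

    def test_constant_control_cost(self):
        times = np.linspace(0, 52, 5201)
        traj = Trajectory(times=times, states=np.zeros((5201, 7)))
        u = np.zeros((5201, 5))
        u[:, 0] = 1.0
        J = objective(traj, ControlPath(times=times, values=u), ObjectiveWeights(w1=0.5))
        assert J == pytest.approx(13.0, rel=1e-12)

    def test_grid_mismatch_rejected(self):
        traj = Trajectory(times=np.linspace(0, 1, 11), states=np.zeros((11, 7)))
        with pytest.raises(ValueError):
            objective(traj, ControlPath.zeros(np.linspace(0, 1, 21)), ObjectiveWeights())


class TestHamiltonian:
    def test_zero_adjoints_leave_running_cost(self, table2):
        w = ObjectiveWeights()
        state = np.array([0.6, 0.2, 0.1, 0.06, 0.02, 0.0, 0.0])
        u = np.full(5, 0.4)
        H = hamiltonian(state, u, np.zeros(7), table2, w)
        expected = 100 * (0.2 + 0.1 + 0.06) + 0.5 * 0.5 * 5 * 0.4**2
        assert H == pytest.approx(expected, rel=1e-12)

    def test_quadratic_in_each_control(self, table2):
        # the second difference of H in u_k recovers w_k exactly
        rng = np.random.default_rng(3)
        state, u, lam = random_point(rng)
        u = np.clip(u, 0.1, 0.9)
        w = ObjectiveWeights()
        for k, wk in enumerate(w.control_costs):
            h = 0.05
            up, um = u.copy(), u.copy()
            up[k] += h
            um[k] -= h
            second = (
                hamiltonian(state, up, lam, table2, w)
                - 2 * hamiltonian(state, u, lam, table2, w)
                + hamiltonian(state, um, lam, table2, w)
            ) / h**2
            assert second == pytest.approx(wk, rel=1e-8)


class TestAdjointSystem:
    def test_origin_with_zero_adjoints(self, table2):
        w = ObjectiveWeights(A1=100, A2=110, A3=120)
        d = adjoint_rhs(np.zeros(7), np.zeros(5), np.zeros(7), table2, w)
        np.testing.assert_allclose(d, [0, -100, -110, -120, 0, 0, 0])

    def test_matches_hamiltonian_gradient(self, table2):
        # dlambda/dt must equal -dH/dstate, checked by central differences
        rng = np.random.default_rng(4)
        w = ObjectiveWeights()
        for _ in range(25):
            state, u, lam = random_point(rng)
            d = adjoint_rhs(state, u, lam, table2, w)
            for j in range(7):
                h = 1e-5 * max(1.0, abs(state[j]))
                hi, lo = state.copy(), state.copy()
                hi[j] += h
                lo[j] -= h
                grad = (
                    hamiltonian(hi, u, lam, table2, w)
                    - hamiltonian(lo, u, lam, table2, w)
                ) / (2 * h)
                assert d[j] == pytest.approx(-grad, abs=1e-8 * max(1.0, abs(grad)))

    def test_relapse_adjoints_couple_to_susceptible_only(self, table2):
        # the Rd adjoint obeys lambda5' = lambda5(mu+gamma1) - lambda1*gamma1
        rng = np.random.default_rng(5)
        state, u, lam = random_point(rng)
        d = adjoint_rhs(state, u, lam, table2, w := ObjectiveWeights())
        p = table2
        assert d[4] == pytest.approx(lam[4] * (p.mu + p.gamma1) - lam[0] * p.gamma1)
        assert d[5] == pytest.approx(lam[5] * (p.mu + p.gamma2) - lam[0] * p.gamma2)
        assert d[6] == pytest.approx(lam[6] * (p.mu + p.gamma3) - lam[0] * p.gamma3)


class TestControlUpdate:
    def test_zero_adjoints_give_zero_controls(self, table2):
        state = np.array([0.6, 0.2, 0.1, 0.06, 0.02, 0.0, 0.0])
        u = control_update(state, np.zeros(7), table2, ObjectiveWeights())
        np.testing.assert_array_equal(u, 0.0)

    def test_large_adjoint_clamps_to_upper_bound(self, table2):
        state = np.array([0.6, 0.2, 0.1, 0.06, 0.02, 0.0, 0.0])
        lam = np.zeros(7)
        lam[1] = 1e6
        u = control_update(state, lam, table2, ObjectiveWeights())
        assert u[3] == 1.0  # recovery effort on drinkers saturates

    def test_interior_values_are_stationary_points(self, table2):
        rng = np.random.default_rng(6)
        w = ObjectiveWeights()
        checked = 0
        for _ in range(200):
            state, _, lam = random_point(rng, adjoint_scale=2.0)
            u = control_update(state, lam, table2, w)
            interior = (u > 2e-3) & (u < 1.0 - 2e-3)
            if not interior.any():
                continue
            for k in np.flatnonzero(interior):
                # H is quadratic in u_k, so the central difference is exact
                # up to roundoff; a wide step keeps roundoff negligible
                h = 1e-3
                up, um = u.copy(), u.copy()
                up[k] += h
                um[k] -= h
                grad = (
                    hamiltonian(state, up, lam, table2, w)
                    - hamiltonian(state, um, lam, table2, w)
                ) / (2 * h)
                assert abs(grad) <= 1e-8
                checked += 1
        assert checked > 20

    def test_custom_bounds_respected(self, table2):
        state = np.array([0.6, 0.2, 0.1, 0.06, 0.02, 0.0, 0.0])
        lam = np.zeros(7)
        lam[1] = 1e6
        bounds = np.column_stack([np.zeros(5), np.full(5, 0.75)])
        u = control_update(state, lam, table2, ObjectiveWeights(), bounds)
        assert u[3] == 0.75

    def test_invalid_bounds_rejected(self, table2):
        state = np.ones(7)
        bounds = np.column_stack([np.zeros(5), np.full(5, 1.5)])
        with pytest.raises(ControlBoundsError):
            control_update(state, np.zeros(7), table2, ObjectiveWeights(), bounds)


class TestSweep:
    # a short cheap scenario exercises the solver mechanics; the full
    # 52-week study is covered by the acceptance suite
    T, STEP = 10.0, 0.05

    def test_zero_state_cost_means_no_action(self, table2, initial_state):
        w = ObjectiveWeights(A1=0.0, A2=0.0, A3=0.0)
        sol = forward_backward_sweep(
            table2, initial_state, w, t1=self.T, step=self.STEP
        )
        assert sol.converged
        np.testing.assert_array_equal(sol.controls.values, 0.0)
        assert sol.objective == pytest.approx(sol.objective_uncontrolled, rel=1e-12)

    def test_pinned_bounds_reproduce_uncontrolled_run(self, table2, initial_state):
        bounds = np.zeros((5, 2))
        sol = forward_backward_sweep(
            table2, initial_state, ObjectiveWeights(),
            t1=self.T, step=self.STEP, bounds=bounds,
        )
        free = simulate(table2, initial_state, self.T, step=self.STEP)
        np.testing.assert_allclose(sol.trajectory.states, free.states, atol=1e-12)
        np.testing.assert_array_equal(sol.controls.values, 0.0)

    def test_control_strictly_improves_objective(self, table2, initial_state):
        sol = forward_backward_sweep(
            table2, initial_state, ObjectiveWeights(), t1=self.T, step=self.STEP
        )
        assert sol.converged
        assert sol.objective < sol.objective_uncontrolled
        assert np.all(sol.controls.values >= 0.0)
        assert np.all(sol.controls.values <= 1.0)

    def test_terminal_transversality(self, table2, initial_state):
        sol = forward_backward_sweep(
            table2, initial_state, ObjectiveWeights(), t1=self.T, step=self.STEP
        )
        np.testing.assert_array_equal(sol.adjoints[-1], 0.0)

    def test_heavier_drinker_cost_does_not_raise_drinker_load(
        self, table2, initial_state
    ):
        w1 = ObjectiveWeights(A1=10.0)
        w2 = ObjectiveWeights(A1=100.0)
        kw = dict(t1=self.T, step=self.STEP)
        s1 = forward_backward_sweep(table2, initial_state, w1, **kw)
        s2 = forward_backward_sweep(table2, initial_state, w2, **kw)
        load1 = np.trapezoid(s1.trajectory.component("D"), s1.trajectory.times)
        load2 = np.trapezoid(s2.trajectory.component("D"), s2.trajectory.times)
        assert load2 <= load1 + 1e-9

    def test_nonconvergence_reported_not_raised(self, table2, initial_state):
        sol = forward_backward_sweep(
            table2, initial_state, ObjectiveWeights(),
            t1=self.T, step=self.STEP, max_iter=2, tol=1e-12,
        )
        assert sol.converged is False
        assert sol.iterations == 2

    def test_bad_solver_settings_rejected(self, table2, initial_state):
        with pytest.raises(ValueError):
            forward_backward_sweep(
                table2, initial_state, ObjectiveWeights(), relaxation=0.0
            )


class TestEfficacy:
    def _pair(self, table2, initial_state):
        base = simulate(table2, initial_state, 5.0, step=0.1)
        return base

    def test_identical_runs_have_zero_efficacy(self, table2, initial_state):
        base = self._pair(table2, initial_state)
        np.testing.assert_allclose(efficacy(base, base, "D"), 0.0, atol=1e-15)

    def test_eradication_has_unit_efficacy(self, table2, initial_state):
        base = self._pair(table2, initial_state)
        zero = Trajectory(times=base.times, states=np.zeros_like(base.states))
        np.testing.assert_allclose(efficacy(zero, base, "D"), 1.0)

    def test_zero_baseline_reported_as_nan(self, table2, initial_state):
        base = self._pair(table2, initial_state)
        dead = Trajectory(times=base.times, states=np.zeros_like(base.states))
        e = efficacy(base, dead, "D")
        assert np.all(np.isnan(e))

    def test_unknown_compartment_and_grid_mismatch(self, table2, initial_state):
        base = self._pair(table2, initial_state)
        with pytest.raises(ValueError):
            efficacy(base, base, "S")
        other = simulate(table2, initial_state, 5.0, step=0.5)
        with pytest.raises(ValueError):
            efficacy(other, base, "D")
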