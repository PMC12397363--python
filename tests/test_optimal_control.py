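"""Pontryagin optimality system and the forward-backward sweep solver."""

import numpy as np
import pytest

from triscav import (
    ControlSolution,
    EconParams,
    adjoint_rhs,
    control_update,
    cost_functional,
    forward_backward_sweep,
    hamiltonian,
    scenario_suite,
)


class TestHamiltonian:
    def test_vanishes_without_effort_or_adjoint(self, control_params):
        p, e, X0 = control_params
        assert hamiltonian(X0, (0, 0, 0), (0, 0), 1.0, p, e) == pytest.approx(0.0)

    def test_stationary_in_effort_at_unclamped_optimum(self, control_params):
        p, e, _ = control_params
        X = (2.0, 2.5, 2.5)
        lam = (0.1, -0.2, 0.05)
        t = 1.3
        E1, E2 = control_update(X, lam, t, p, e)
        assert 0 < E1 < e.E1max and 0 < E2 < e.E2max   # interior optimum
        h = 1e-7
        dH1 = (
            hamiltonian(X, lam, (E1 + h, E2), t, p, e)
            - hamiltonian(X, lam, (E1 - h, E2), t, p, e)
        ) / (2 * h)
        dH2 = (
            hamiltonian(X, lam, (E1, E2 + h), t, p, e)
            - hamiltonian(X, lam, (E1, E2 - h), t, p, e)
        ) / (2 * h)
        assert abs(dH1) < 1e-8 and abs(dH2) < 1e-8


class TestAdjointRhs:
    def test_zero_adjoint_zero_effort_gives_zero(self, control_params):
        p, e, X0 = control_params
        assert np.allclose(adjoint_rhs(X0, (0, 0, 0), (0, 0), 2.0, p, e), 0.0)

    def test_matches_canonical_equations_oracle(self, control_params, rng):
        """dlambda/dT must equal -dH/dX by construction; checked against a
        finite-difference Hamiltonian gradient."""
        p, e, _ = control_params
        for _ in range(20):
            X = rng.uniform(0.2, 5.0, 3)
            lam = rng.uniform(-1, 1, 3)
            E = rng.uniform(0, 1, 2)
            t = rng.uniform(0, e.Tf)
            g = adjoint_rhs(X, lam, E, t, p, e)
            h = 1e-6
            for j in range(3):
                dX = np.zeros(3)
                dX[j] = h
                fd = -(
                    hamiltonian(X + dX, lam, E, t, p, e)
                    - hamiltonian(X - dX, lam, E, t, p, e)
                ) / (2 * h)
                assert g[j] == pytest.approx(fd, abs=2e-6)

    def test_revenue_terms_vanish_with_populations(self, control_params):
        p, e, _ = control_params
        g = adjoint_rhs((1.0, 0.0, 0.0), (0.3, 0.4, 0.5), (0.5, 0.5), 1.0, p, e)
        # with X2 = X3 = 0 the revenue gradients drop out; remaining terms
        # are the linearized dynamics weighted by the adjoints
        g2 = adjoint_rhs((1.0, 0.0, 0.0), (0.3, 0.4, 0.5), (0.0, 0.0), 1.0, p, e)
        assert np.allclose(g, g2)


class TestControlUpdate:
    def test_unprofitable_harvest_clamps_to_zero(self, control_params):
        p, e, _ = control_params
        # p1 q1 X2^2 = 0.5*0.25 << C1 = 1 and lambda2 >= 0
        E1, _ = control_update((1.0, 0.5, 1.0), (0.0, 0.1, 0.0), 0.0, p, e)
        assert E1 == 0.0

    def test_large_price_saturates_at_cap(self, control_params):
        p, _, _ = control_params
        e = EconParams(p1=500.0, E1max=0.7, Tf=5.0)
        E1, _ = control_update((1.0, 2.0, 1.0), (0.0, 0.0, 0.0), 0.0, p, e)
        assert E1 == 0.7

    def test_interior_formula_plug_in(self):
        # E1* = (p1 q1 X2^2 - C1) / (2 nu1 q1^2 X2^4) at t=0, lambda2=0
        p_dim = __import__("triscav").DimParams(q1=0.5)
        e = EconParams(p1=1.0, C1=1.0, nu1_econ=1.0, E1max=10.0)
        E1, _ = control_update((1.0, 2.0, 0.0), (0.0, 0.0, 0.0), 0.0, p_dim, e)
        assert E1 == pytest.approx((0.5 * 4 - 1) / (2 * 0.25 * 16))

    def test_extinct_population_means_no_effort(self, control_params):
        p, e, _ = control_params
        E1, E2 = control_update((1.0, 0.0, 1e-12), (0, -5.0, -5.0), 0.0, p, e)
        assert E1 == 0.0 and E2 == 0.0


class TestForwardBackwardSweep:
    def test_unprofitable_problem_converges_to_zero_effort(self, control_params):
        p, _, X0 = control_params
        e = EconParams(C1=1e6, C2=1e6, Tf=5.0)
        sol = forward_backward_sweep(p, e, X0, n_grid=301)
        assert sol.converged
        assert np.all(sol.E1 == 0) and np.all(sol.E2 == 0)
        assert sol.J == pytest.approx(0.0, abs=1e-12)

    def test_transversality_and_admissibility(self, control_params):
        p, e, X0 = control_params
        sol = forward_backward_sweep(p, e, X0, n_grid=501)
        assert sol.converged
        assert np.all(sol.adjoints[-1] == 0.0)
        assert np.all((sol.E1 >= 0) & (sol.E1 <= e.E1max))
        assert np.all((sol.E2 >= 0) & (sol.E2 <= e.E2max))
        assert sol.update_history[-1] < 1e-6

    def test_clamped_stationarity_along_trajectory(self, control_params):
        p, e, X0 = control_params
        sol = forward_backward_sweep(p, e, X0, n_grid=501)
        for i in range(0, 501, 50):
            u1, u2 = control_update(sol.states[i], sol.adjoints[i], sol.t[i], p, e)
            assert sol.E1[i] == pytest.approx(u1, abs=1e-4)
            assert sol.E2[i] == pytest.approx(u2, abs=1e-4)

    def test_grid_refinement_changes_J_little(self, control_params):
        p, e, X0 = control_params
        J_coarse = forward_backward_sweep(p, e, X0, n_grid=501).J
        J_fine = forward_backward_sweep(p, e, X0, n_grid=1001).J
        assert abs(J_fine - J_coarse) / abs(J_fine) < 1e-3


class TestCostFunctional:
    def test_zero_controls_zero_revenue(self, control_params):
        p, e, _ = control_params
        t = np.linspace(0, e.Tf, 101)
        states = np.tile([1.0, 2.0, 3.0], (101, 1))
        sol = ControlSolution(
            t=t, states=states, adjoints=np.zeros((101, 3)),
            E1=np.zeros(101), E2=np.zeros(101), J=0.0,
            iterations=0, converged=True,
        )
        assert cost_functional(sol, e, p) == 0.0

    def test_constant_toy_matches_closed_form(self, control_params):
        p, _, _ = control_params
        e = EconParams(delta1=0.1, Tf=2.0)
        t = np.linspace(0, e.Tf, 2001)
        X2, X3, E1 = 2.0, 1.0, 0.05
        states = np.tile([1.0, X2, X3], (2001, 1))
        sol = ControlSolution(
            t=t, states=states, adjoints=np.zeros((2001, 3)),
            E1=np.full(2001, E1), E2=np.zeros(2001), J=0.0,
            iterations=0, converged=True,
        )
        y1 = p.q1 * E1 * X2**2
        integrand0 = (e.p1 - e.nu1_econ * y1) * y1 - e.C1 * E1
        expected = integrand0 * (1 - np.exp(-e.delta1 * e.Tf)) / e.delta1
        assert cost_functional(sol, e, p) == pytest.approx(expected, rel=1e-9)

    def test_quadrature_cross_check(self, control_params):
        from scipy.integrate import trapezoid

        from triscav.optimal_control import _integrand

        p, e, X0 = control_params
        sol = forward_backward_sweep(p, e, X0, n_grid=1001)
        vals = _integrand(
            sol.states[:, 1], sol.states[:, 2], sol.E1, sol.E2, sol.t, p, e
        )
        J_trap = trapezoid(vals, sol.t)
        assert abs(J_trap - sol.J) / max(1.0, abs(sol.J)) < 1e-6

    def test_mismatched_grids_rejected(self, control_params):
        p, e, _ = control_params
        t = np.linspace(0, e.Tf, 11)
        sol = ControlSolution(
            t=t, states=np.ones((11, 3)), adjoints=np.zeros((11, 3)),
            E1=np.zeros(10), E2=np.zeros(11), J=0.0, iterations=0, converged=True,
        )
        with pytest.raises(ValueError):
            cost_functional(sol, e, p)


class TestScenarioSuite:
    def test_ordering_and_positivity(self, control_params):
        p, e, X0 = control_params
        sols = scenario_suite(p, e, X0, n_grid=501)
        assert sols["none"].J == pytest.approx(0.0, abs=1e-12)
        assert sols["e1"].J >= -1e-9 and sols["e2"].J >= -1e-9
        assert sols["both"].J >= max(sols["e1"].J, sols["e2"].J) - 1e-6
        for sol in sols.values():
            assert np.all(sol.states[:, 0] > 0)   # prey never extinct

    def test_excluded_controls_pinned_to_zero(self, control_params):
        p, e, X0 = control_params
        sols = scenario_suite(p, e, X0, n_grid=301)
        assert np.all(sols["e1"].E2 == 0)
        assert np.all(sols["e2"].E1 == 0)
        assert np.all(sols["none"].E1 == 0) and np.all(sols["none"].E2 == 0)
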