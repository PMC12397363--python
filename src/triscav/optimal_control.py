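"""Optimal quadratic harvesting by Pontryagin's principle.

The harvesting efforts on predator and scavenger become time-dependent
controls ``E1(T), E2(T)`` on a fixed horizon ``[0, Tf]``, chosen to maximize
the discounted net revenue

    J = int_0^Tf e^{-delta1 T} [ (p1 - nu1 q1 E1 X2^2) q1 E1 X2^2
                               + (p2 - nu2 q2 E2 X3^2) q2 E2 X3^2
                               - C1 E1 - C2 E2 ] dT

subject to the dimensional population dynamics with quadratic harvesting.
Here ``p_i`` are prices per unit biomass, ``C_i`` costs per unit effort,
``delta1`` the annual discount rate and ``nu_i`` economic (diminishing
returns) constants — distinct from the dimensionless harvesting rates of the
rescaled model, which reuse the same symbols.

Pontryagin's maximum principle couples the states to present-value adjoints
``dlambda/dT = -dH/dX`` with transversality ``lambda(Tf) = 0``, and gives the
clamped closed-form controls

    E1* = clip( [e^{-delta1 T}(p1 q1 X2^2 - C1) - lambda2 q1 X2^2]
                / (2 e^{-delta1 T} nu1 q1^2 X2^4), 0, E1max )

(and symmetrically for ``E2*`` with ``X3, lambda3``).  The two-point boundary
value problem is solved by the forward-backward sweep: integrate states
forward, adjoints backward, update controls from the stationarity formula
with relaxation, iterate to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import simpson

from .core_model import DimParams

__all__ = [
    "EconParams",
    "ControlSolution",
    "hamiltonian",
    "adjoint_rhs",
    "control_update",
    "forward_backward_sweep",
    "cost_functional",
    "scenario_suite",
    "SCENARIOS",
]

SCENARIOS = ("none", "e1", "e2", "both")

# Below this population the harvesting stationarity formula (which divides by
# X^2 and X^4) is replaced by zero effort: harvesting nothing still costs
# C*E > 0, so zero is optimal there.
_POP_FLOOR = 1e-8


@dataclass(frozen=True)
class EconParams:
    """Economic parameters of the revenue functional."""

    p1: float = 1.0          # price per unit predator biomass
    p2: float = 1.0          # price per unit scavenger biomass
    C1: float = 1.0          # cost per unit predator effort
    C2: float = 1.0          # cost per unit scavenger effort
    delta1: float = 0.05     # annual discount rate
    nu1_econ: float = 1.0    # economic constant (diminishing returns), predator
    nu2_econ: float = 1.0    # economic constant, scavenger
    E1max: float = 1.0
    E2max: float = 1.0
    Tf: float = 5.0          # horizon, years

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "C1", "C2", "delta1", "nu1_econ", "nu2_econ"):
            if getattr(self, name) < 0:
                raise ValueError(f"economic parameter {name!r} must be >= 0")
        if not (self.Tf > 0 and self.E1max > 0 and self.E2max > 0):
            raise ValueError("Tf and effort caps must be positive")


@dataclass
class ControlSolution:
    t: np.ndarray
    states: np.ndarray           # (n, 3): X1, X2, X3
    adjoints: np.ndarray         # (n, 3): lambda1..3
    E1: np.ndarray
    E2: np.ndarray
    J: float
    iterations: int
    converged: bool
    update_history: list = field(default_factory=list)   # sup-norm control changes


def _integrand(X2, X3, E1, E2, t, p: DimParams, e: EconParams):
    """Discounted net-revenue integrand of J (vectorized)."""
    disc = np.exp(-e.delta1 * np.asarray(t, dtype=float))
    y1 = p.q1 * E1 * X2 ** 2
    y2 = p.q2 * E2 * X3 ** 2
    return disc * ((e.p1 - e.nu1_econ * y1) * y1 + (e.p2 - e.nu2_econ * y2) * y2
                   - e.C1 * E1 - e.C2 * E2)


def _state_rhs(X, E1, E2, p: DimParams):
    X1, X2, X3 = X
    D = 1.0 + p.k1 * X1 + p.k2 * X2 + p.k3 * X1 * X2
    return np.array([
        X1 * (p.r - p.k * X1) - p.a * X1 * X2 / D - p.b * X1 * X3,
        p.c * X1 * X2 / D - p.d * X2 - p.q1 * E1 * X2 ** 2,
        p.l * X1 * X3 + p.m * X2 * X3 - p.n * X3 - p.q2 * E2 * X3 ** 2,
    ])


def hamiltonian(
    state: Sequence[float],
    adjoint: Sequence[float],
    controls: Sequence[float],
    t: float,
    p: DimParams,
    e: EconParams,
) -> float:
    """Present-value Hamiltonian ``H = L + lambda . dX/dT``."""
    X1, X2, X3 = state
    E1, E2 = controls
    L = float(_integrand(X2, X3, E1, E2, t, p, e))
    f = _state_rhs(np.asarray(state, dtype=float), E1, E2, p)
    return L + float(np.dot(adjoint, f))


def adjoint_rhs(
    state: Sequence[float],
    adjoint: Sequence[float],
    controls: Sequence[float],
    t: float,
    p: DimParams,
    e: EconParams,
) -> np.ndarray:
    """Adjoint equations ``dlambda/dT = -dH/dX`` (present-value convention).

    Derived directly from the canonical equations of the Hamiltonian; the
    discounted revenue gradients enter the predator and scavenger adjoints.
    """
    X1, X2, X3 = state
    l1, l2, l3 = adjoint
    E1, E2 = controls
    D = 1.0 + p.k1 * X1 + p.k2 * X2 + p.k3 * X1 * X2
    D2 = D * D
    dxy_dX1 = X2 * (1.0 + p.k2 * X2) / D2    # d(X1 X2 / D)/dX1
    dxy_dX2 = X1 * (1.0 + p.k1 * X1) / D2    # d(X1 X2 / D)/dX2
    df1_dX1 = p.r - 2.0 * p.k * X1 - p.a * dxy_dX1 - p.b * X3
    df1_dX2 = -p.a * dxy_dX2
    df1_dX3 = -p.b * X1
    df2_dX1 = p.c * dxy_dX1
    df2_dX2 = p.c * dxy_dX2 - p.d - 2.0 * p.q1 * E1 * X2
    df3_dX1 = p.l * X3
    df3_dX2 = p.m * X3
    df3_dX3 = p.l * X1 + p.m * X2 - p.n - 2.0 * p.q2 * E2 * X3
    disc = np.exp(-e.delta1 * t)
    y1 = p.q1 * E1 * X2 ** 2
    y2 = p.q2 * E2 * X3 ** 2
    dL_dX2 = disc * (2.0 * e.p1 * p.q1 * E1 * X2
                     - 4.0 * e.nu1_econ * p.q1 ** 2 * E1 ** 2 * X2 ** 3)
    dL_dX3 = disc * (2.0 * e.p2 * p.q2 * E2 * X3
                     - 4.0 * e.nu2_econ * p.q2 ** 2 * E2 ** 2 * X3 ** 3)
    return np.array([
        -(l1 * df1_dX1 + l2 * df2_dX1 + l3 * df3_dX1),
        -(dL_dX2 + l1 * df1_dX2 + l2 * df2_dX2 + l3 * df3_dX2),
        -(dL_dX3 + l1 * df1_dX3 + l3 * df3_dX3),
    ])


def control_update(
    state: Sequence[float],
    adjoint: Sequence[float],
    t: float,
    p: DimParams,
    e: EconParams,
) -> tuple[float, float]:
    """Clamped stationarity controls ``(E1*, E2*)`` at one time point.

    Zero effort when the harvested population is (numerically) extinct.
    """
    X1, X2, X3 = state
    _, l2, l3 = adjoint
    disc = np.exp(-e.delta1 * t)
    if X2 > _POP_FLOOR and e.nu1_econ > 0:
        num = disc * (e.p1 * p.q1 * X2 ** 2 - e.C1) - l2 * p.q1 * X2 ** 2
        den = 2.0 * disc * e.nu1_econ * p.q1 ** 2 * X2 ** 4
        E1 = min(max(0.0, num / den), e.E1max)
    else:
        E1 = 0.0
    if X3 > _POP_FLOOR and e.nu2_econ > 0:
        num = disc * (e.p2 * p.q2 * X3 ** 2 - e.C2) - l3 * p.q2 * X3 ** 2
        den = 2.0 * disc * e.nu2_econ * p.q2 ** 2 * X3 ** 4
        E2 = min(max(0.0, num / den), e.E2max)
    else:
        E2 = 0.0
    return E1, E2


def _forward_states(t, X0, E1, E2, p: DimParams) -> np.ndarray:
    """RK4 forward integration of the states on the fixed grid."""
    n = t.size
    X = np.empty((n, 3))
    X[0] = X0
    for i in range(n - 1):
        h = t[i + 1] - t[i]
        e1a, e1m, e1b = E1[i], 0.5 * (E1[i] + E1[i + 1]), E1[i + 1]
        e2a, e2m, e2b = E2[i], 0.5 * (E2[i] + E2[i + 1]), E2[i + 1]
        x = X[i]
        k1 = _state_rhs(x, e1a, e2a, p)
        k2 = _state_rhs(np.clip(x + 0.5 * h * k1, 0.0, None), e1m, e2m, p)
        k3 = _state_rhs(np.clip(x + 0.5 * h * k2, 0.0, None), e1m, e2m, p)
        k4 = _state_rhs(np.clip(x + h * k3, 0.0, None), e1b, e2b, p)
        X[i + 1] = np.clip(x + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0, None)
    return X


def _backward_adjoints(t, X, E1, E2, p: DimParams, e: EconParams) -> np.ndarray:
    """RK4 backward integration of the adjoints from lambda(Tf) = 0."""
    n = t.size
    lam = np.empty((n, 3))
    lam[-1] = 0.0
    for i in range(n - 2, -1, -1):
        h = t[i + 1] - t[i]
        xb, xa = X[i + 1], X[i]
        xm = 0.5 * (xa + xb)
        e1b, e1a = E1[i + 1], E1[i]
        e2b, e2a = E2[i + 1], E2[i]
        e1m, e2m = 0.5 * (e1a + e1b), 0.5 * (e2a + e2b)
        tb, tm, ta = t[i + 1], 0.5 * (t[i] + t[i + 1]), t[i]
        lb = lam[i + 1]
        k1 = adjoint_rhs(xb, lb, (e1b, e2b), tb, p, e)
        k2 = adjoint_rhs(xm, lb - 0.5 * h * k1, (e1m, e2m), tm, p, e)
        k3 = adjoint_rhs(xm, lb - 0.5 * h * k2, (e1m, e2m), tm, p, e)
        k4 = adjoint_rhs(xa, lb - h * k3, (e1a, e2a), ta, p, e)
        lam[i] = lb - h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return lam


def cost_functional(solution: ControlSolution, e: EconParams, p: DimParams) -> float:
    """Discounted revenue J of a solution by Simpson quadrature."""
    X2 = solution.states[:, 1]
    X3 = solution.states[:, 2]
    if not (solution.t.size == X2.size == solution.E1.size == solution.E2.size):
        raise ValueError("time grid and trajectories must share one length")
    vals = _integrand(X2, X3, solution.E1, solution.E2, solution.t, p, e)
    return float(simpson(vals, x=solution.t))


def forward_backward_sweep(
    p: DimParams,
    e: EconParams,
    X0: Sequence[float],
    n_grid: int = 2001,
    tol: float = 1e-6,
    j_tol: float = 1e-8,
    max_iter: int = 200,
    relaxation: float = 0.5,
    use_E1: bool = True,
    use_E2: bool = True,
) -> ControlSolution:
    """Forward-backward sweep solver for the harvesting control problem.

    Iterates state-forward / adjoint-backward / relaxed control update
    (``E_new = (1-w) E_old + w E_formula``) until the sup-norm control change
    falls below ``tol`` and the relative change of J below ``j_tol``.
    Scenario flags pin an excluded control to zero throughout.
    """
    X0 = np.asarray(X0, dtype=float)
    if np.any(X0 <= 0):
        raise ValueError("initial populations must be positive")
    t = np.linspace(0.0, e.Tf, n_grid)
    E1 = np.zeros(n_grid)
    E2 = np.zeros(n_grid)
    history: list[float] = []
    J_old = None
    converged = False
    it = 0
    X = _forward_states(t, X0, E1, E2, p)
    lam = _backward_adjoints(t, X, E1, E2, p, e)
    for it in range(1, max_iter + 1):
        X = _forward_states(t, X0, E1, E2, p)
        lam = _backward_adjoints(t, X, E1, E2, p, e)
        E1_new = np.empty(n_grid)
        E2_new = np.empty(n_grid)
        for i in range(n_grid):
            u1, u2 = control_update(X[i], lam[i], t[i], p, e)
            E1_new[i] = u1 if use_E1 else 0.0
            E2_new[i] = u2 if use_E2 else 0.0
        E1_next = (1.0 - relaxation) * E1 + relaxation * E1_new
        E2_next = (1.0 - relaxation) * E2 + relaxation * E2_new
        change = max(
            float(np.max(np.abs(E1_next - E1))), float(np.max(np.abs(E2_next - E2)))
        )
        history.append(change)
        E1, E2 = E1_next, E2_next
        sol_tmp = ControlSolution(t, X, lam, E1, E2, 0.0, it, False, history)
        J = cost_functional(sol_tmp, e, p)
        if change < tol and J_old is not None and abs(J - J_old) <= j_tol * max(
            1.0, abs(J)
        ):
            converged = True
            J_old = J
            break
        J_old = J
    X = _forward_states(t, X0, E1, E2, p)
    lam = _backward_adjoints(t, X, E1, E2, p, e)
    sol = ControlSolution(
        t=t, states=X, adjoints=lam, E1=E1, E2=E2, J=0.0,
        iterations=it, converged=converged, update_history=history,
    )
    sol.J = cost_functional(sol, e, p)
    return sol


def scenario_suite(
    p: DimParams,
    e: EconParams,
    X0: Sequence[float],
    n_grid: int = 2001,
    **kwargs,
) -> dict[str, ControlSolution]:
    """Solve the four effort scenarios: no control, E1 only, E2 only, both.

    The excluded control is pinned to zero; the no-control scenario is a plain
    simulation with J = 0.  Larger admissible sets can only increase J, so
    J(both) >= J(e1), J(e2) >= J(none) = 0 up to solver tolerance.
    """
    out: dict[str, ControlSolution] = {}
    flags = {
        "none": (False, False),
        "e1": (True, False),
        "e2": (False, True),
        "both": (True, True),
    }
    for name in SCENARIOS:
        u1, u2 = flags[name]
        if not u1 and not u2:
            t = np.linspace(0.0, e.Tf, n_grid)
            E = np.zeros(n_grid)
            X = _forward_states(t, np.asarray(X0, dtype=float), E, E, p)
            lam = _backward_adjoints(t, X, E, E, p, e)
            sol = ControlSolution(
                t=t, states=X, adjoints=lam, E1=E.copy(), E2=E.copy(),
                J=0.0, iterations=0, converged=True, update_history=[],
            )
            sol.J = cost_functional(sol, e, p)
        else:
            sol = forward_backward_sweep(
                p, e, X0, n_grid=n_grid, use_E1=u1, use_E2=u2, **kwargs
            )
        out[name] = sol
    return out
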