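"""Core prey-predator-scavenger model.

A three-species food web: prey ``x`` grows logistically and is attacked by a
predator ``y`` through a Crowley-Martin functional response (feeding saturates
in prey *and* is depressed by predator interference), and by a scavenger ``z``
through mass action.  The scavenger also gains from naturally dead predators
without affecting the live predator population.  Predator and scavenger are
subject to quadratic harvesting (removal ~ effort x stock^2).

Two parameterizations are supported: the dimensional model in populations
``(X1, X2, X3)`` and the rescaled dimensionless model in ``(x, y, z)``.  The
rescaling ``x = (c/r) X1``, ``y = (a/r) X2``, ``z = (b/r) X3``, ``t = r T``
maps one onto the other; :func:`nondimensionalize` implements the parameter
mapping and the two right-hand sides are consistent under it.

Dimensionless model::

    dx/dt = x (1 - gamma x) - x y / (1 + A1 x + A2 y + A3 x y) - x z
    dy/dt = x y / (1 + A1 x + A2 y + A3 x y) - delta y - nu1 y^2
    dz/dt = alpha x z + beta y z - mu z - nu2 z^2

Every right-hand side component carries its own state factor, so the
coordinate planes are invariant: a population that starts at zero stays at
zero, and positive initial data stay positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DimParams",
    "NonDimParams",
    "BoundednessReport",
    "Trajectory",
    "crowley_martin",
    "per_capita_nondim",
    "rhs_nondim",
    "rhs_dim",
    "nondimensionalize",
    "boundedness_check",
    "integrate_orbit",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
    "UNDERSHOOT_CLIP",
]

# Integrator defaults.  Period-doubling windows of this model are narrow
# (widths of order 1e-3 in the harvesting rate) and orbit classification is
# tolerance sensitive, so the defaults are tight.
DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-11
# Coordinates whose magnitude falls below this after an output sample are
# snapped to 0: floating-point drift must not cross the invariant planes.
UNDERSHOOT_CLIP = 1e-12


def _require_nonneg(obj, names: Sequence[str]) -> None:
    for name in names:
        v = getattr(obj, name)
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"parameter {name!r} must be finite and >= 0, got {v}")


def _require_pos(obj, names: Sequence[str]) -> None:
    for name in names:
        v = getattr(obj, name)
        if not v > 0:
            raise ValueError(f"parameter {name!r} must be > 0, got {v}")


@dataclass(frozen=True)
class DimParams:
    """Dimensional model parameters.

    r: prey intrinsic growth rate (1/time); k: prey self-limitation;
    a, b: predator/scavenger attack rates on prey; c: conversion efficiency
    into predator growth; d, n: predator/scavenger mortalities; k1, k2, k3:
    functional-response coefficients (handling, predator interference, joint
    interference); l, m: scavenger benefit rates from killed prey and from
    predator carcasses; q1, q2: catchabilities; E1, E2: constant efforts.
    """

    r: float = 1.0
    k: float = 1.0
    a: float = 1.0
    b: float = 1.0
    c: float = 1.0
    d: float = 0.0
    n: float = 0.0
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    l: float = 0.0
    m: float = 0.0
    q1: float = 0.0
    q2: float = 0.0
    E1: float = 0.0
    E2: float = 0.0

    def __post_init__(self) -> None:
        _require_nonneg(self, [f.name for f in fields(self)])
        # the rescaling divides by r, a, b, c
        _require_pos(self, ["r", "a", "b", "c"])


@dataclass(frozen=True)
class NonDimParams:
    """Dimensionless model parameters.

    gamma: prey self-limitation; A1, A2, A3: Crowley-Martin coefficients;
    delta, mu: predator/scavenger mortalities; alpha, beta: scavenger benefit
    rates from prey and carcasses; nu1, nu2: quadratic harvesting rates on
    predator and scavenger.
    """

    gamma: float = 1.0
    A1: float = 0.0
    A2: float = 0.0
    A3: float = 0.0
    delta: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0
    mu: float = 0.0
    nu1: float = 0.0
    nu2: float = 0.0

    def __post_init__(self) -> None:
        _require_nonneg(self, [f.name for f in fields(self)])
        _require_pos(self, ["gamma"])

    def replace(self, **changes) -> "NonDimParams":
        """Return a copy with the given fields replaced."""
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(changes)
        return NonDimParams(**d)


@dataclass(frozen=True)
class BoundednessReport:
    """Verdict of the sufficient boundedness condition beta^2 < 4 alpha nu1 nu2.

    The condition is sufficient only: ``condition_holds=False`` does not imply
    unbounded solutions.  ``M = min(delta, mu)`` and ``M1 = (1+M)^2/(4 M gamma)``
    is the asymptotic bound on ``x + y + z/alpha`` when the condition holds.
    """

    condition_holds: bool
    margin: float          # 4*alpha*nu1*nu2 - beta^2
    M: float
    M1: float | None       # None when M == 0 (bound undefined)
    bound_defined: bool


@dataclass
class Trajectory:
    """Sampled orbit of the dimensionless model."""

    t: np.ndarray
    states: np.ndarray     # shape (n, 3), columns x, y, z
    success: bool
    message: str = ""

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 2]


def crowley_martin(x: float, y: float, A1: float, A2: float, A3: float) -> float:
    """Crowley-Martin interaction rate ``x y / (1 + A1 x + A2 y + A3 x y)``.

    With ``A1 = A2 = A3 = 0`` this is mass action; ``A2, A3 > 0`` encode
    predator interference that depresses feeding even at high prey density.
    """
    if x < 0 or y < 0:
        raise ValueError(f"densities must be >= 0, got x={x}, y={y}")
    if A1 < 0 or A2 < 0 or A3 < 0:
        raise ValueError("Crowley-Martin coefficients must be >= 0")
    return x * y / (1.0 + A1 * x + A2 * y + A3 * x * y)


def per_capita_nondim(state: Sequence[float], p: NonDimParams):
    """Per-capita growth factors ``(f1, g1, h1)`` of the dimensionless model.

    ``dx/dt = x f1``, ``dy/dt = y g1``, ``dz/dt = z h1``.
    """
    x, y, z = state
    B = 1.0 + p.A1 * x + p.A2 * y + p.A3 * x * y
    f1 = (1.0 - p.gamma * x) - y / B - z
    g1 = x / B - p.delta - p.nu1 * y
    h1 = p.alpha * x + p.beta * y - p.mu - p.nu2 * z
    return f1, g1, h1


def rhs_nondim(state: Sequence[float], p: NonDimParams) -> np.ndarray:
    """Right-hand side of the dimensionless model at ``state = (x, y, z)``.

    Each component is the state coordinate times its per-capita factor, so a
    zero coordinate has zero derivative (invariant coordinate planes).
    """
    x, y, z = state
    if x < 0 or y < 0 or z < 0:
        raise ValueError(f"state must lie in the nonnegative octant, got {tuple(state)}")
    f1, g1, h1 = per_capita_nondim(state, p)
    return np.array([x * f1, y * g1, z * h1])


def rhs_dim(
    state: Sequence[float],
    p: DimParams,
    E1: float | None = None,
    E2: float | None = None,
) -> np.ndarray:
    """Right-hand side of the dimensional model at ``state = (X1, X2, X3)``.

    ``E1``/``E2`` override the constant efforts of ``p`` (used for
    time-dependent harvesting in the optimal-control problem); harvesting is
    quadratic in the stock, ``q E X^2``.
    """
    X1, X2, X3 = state
    if X1 < 0 or X2 < 0 or X3 < 0:
        raise ValueError(f"populations must be >= 0, got {tuple(state)}")
    e1 = p.E1 if E1 is None else E1
    e2 = p.E2 if E2 is None else E2
    if e1 < 0 or e2 < 0:
        raise ValueError("efforts must be >= 0")
    D = 1.0 + p.k1 * X1 + p.k2 * X2 + p.k3 * X1 * X2
    dX1 = X1 * (p.r - p.k * X1) - p.a * X1 * X2 / D - p.b * X1 * X3
    dX2 = p.c * X1 * X2 / D - p.d * X2 - p.q1 * e1 * X2 ** 2
    dX3 = p.l * X1 * X3 + p.m * X2 * X3 - p.n * X3 - p.q2 * e2 * X3 ** 2
    return np.array([dX1, dX2, dX3])


def nondimensionalize(p: DimParams) -> NonDimParams:
    """Map dimensional parameters to the dimensionless set.

    gamma = k/c, A1 = k1 r/c, A2 = k2 r/a, A3 = k3 r^2/(c a), delta = d/r,
    mu = n/r, alpha = l/c, beta = m/a, nu1 = q1 E1 / a, nu2 = q2 E2 / b.

    The harvesting groups follow from substituting ``y = (a/r) X2`` and
    ``z = (b/r) X3`` into the quadratic harvesting terms: the predator group
    divides by the predator scale ``a`` and the scavenger group by the
    scavenger scale ``b``.  (This is the unique mapping under which the two
    right-hand sides agree; see the rescaling consistency test.)
    """
    return NonDimParams(
        gamma=p.k / p.c,
        A1=p.k1 * p.r / p.c,
        A2=p.k2 * p.r / p.a,
        A3=p.k3 * p.r ** 2 / (p.c * p.a),
        delta=p.d / p.r,
        mu=p.n / p.r,
        alpha=p.l / p.c,
        beta=p.m / p.a,
        nu1=p.q1 * p.E1 / p.a,
        nu2=p.q2 * p.E2 / p.b,
    )


def boundedness_check(p: NonDimParams) -> BoundednessReport:
    """Evaluate the sufficient boundedness condition ``beta^2 < 4 alpha nu1 nu2``.

    When it holds, ``x + y + z/alpha`` is eventually bounded by
    ``M1 = (1+M)^2 / (4 M gamma)`` with ``M = min(delta, mu)``.  Failure of the
    condition proves nothing (it is only sufficient).
    """
    margin = 4.0 * p.alpha * p.nu1 * p.nu2 - p.beta ** 2
    M = min(p.delta, p.mu)
    if M > 0:
        M1 = (1.0 + M) ** 2 / (4.0 * M * p.gamma)
        defined = True
    else:
        M1 = None
        defined = False
    return BoundednessReport(
        condition_holds=margin > 0,
        margin=margin,
        M=M,
        M1=M1,
        bound_defined=defined,
    )


def integrate_orbit(
    p: NonDimParams,
    x0: Sequence[float],
    t_end: float,
    *,
    t_start: float = 0.0,
    n_samples: int | None = None,
    t_eval: np.ndarray | None = None,
    method: str = "LSODA",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    dense_output: bool = False,
):
    """Integrate the dimensionless model from ``x0`` over ``[t_start, t_end]``.

    Positive components are integrated in log coordinates, so positivity and
    the invariance of the coordinate planes hold structurally: a coordinate
    that starts at zero stays exactly zero, and a positive one can underflow
    to zero but never cross it.  Output samples below the underflow clip
    (1e-12 in magnitude) are snapped to zero.  Deterministic given settings.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (3,):
        raise ValueError("x0 must have three components")
    if np.any(x0 < 0):
        raise ValueError("x0 must lie in the nonnegative octant")
    if not t_end > t_start:
        raise ValueError("t_end must exceed t_start")
    if t_eval is None and n_samples is not None:
        t_eval = np.linspace(t_start, t_end, n_samples)

    mask = x0 > 0.0
    w0 = np.where(mask, np.log(np.where(mask, x0, 1.0)), 0.0)

    def f(t, w):
        with np.errstate(over="ignore"):
            s = np.where(mask, np.exp(w), 0.0)
        x, y, z = s
        B = 1.0 + p.A1 * x + p.A2 * y + p.A3 * x * y
        percap = (
            (1.0 - p.gamma * x) - y / B - z,
            x / B - p.delta - p.nu1 * y,
            p.alpha * x + p.beta * y - p.mu - p.nu2 * z,
        )
        return np.where(mask, percap, 0.0)

    sol = solve_ivp(
        f,
        (t_start, t_end),
        w0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=dense_output,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE solver failed: {sol.message} (reached t={sol.t[-1] if sol.t.size else t_start})"
        )
    with np.errstate(over="ignore"):
        states = np.where(mask, np.exp(sol.y.T), 0.0)
    states[np.abs(states) < UNDERSHOOT_CLIP] = 0.0
    traj = Trajectory(t=sol.t, states=states, success=True, message=sol.message)
    if dense_output:
        traj.log_sol = sol.sol  # type: ignore[attr-defined]
        traj.log_mask = mask  # type: ignore[attr-defined]
    return traj
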