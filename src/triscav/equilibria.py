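"""Equilibrium points of the dimensionless prey-predator-scavenger model.

The model has up to five kinds of equilibria:

* ``P0 = (0, 0, 0)`` - total extinction (always present),
* ``P1 = (1/gamma, 0, 0)`` - prey-only,
* ``P2 = (xbar, ybar, 0)`` - scavenger-free coexistence of prey and predator,
* ``P3 = (xhat, 0, zhat)`` - predator-free coexistence of prey and scavenger
  (closed form, exists iff ``alpha > gamma mu``),
* ``Pstar = (x*, y*, z*)`` - interior coexistence, found numerically.

``P2`` solves the pair ``(1 - gamma x) = y/B`` and ``x/B = delta + nu1 y``
with ``B = 1 + A1 x + A2 y + A3 x y``; depending on parameters there may be
0, 1, or 2 positive roots, so the solver brackets sign changes of the reduced
scalar equation along ``x in (0, 1/gamma)``.  The interior point has no closed
form and is located by a seeded Latin-hypercube multi-start Newton search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, root
from scipy.stats import qmc

from .core_model import NonDimParams, per_capita_nondim, rhs_nondim

__all__ = [
    "EquilibriumPoint",
    "equilibrium_trivial_axial",
    "equilibrium_scavenger_free",
    "equilibrium_predator_free",
    "equilibrium_interior",
    "interior_from_guess",
    "scavenger_free_from_guess",
    "all_equilibria",
    "RESIDUAL_TOL",
    "POSITIVITY_TOL",
    "DEDUP_TOL",
]

RESIDUAL_TOL = 1e-10     # max |rhs| accepted for a reported equilibrium
POSITIVITY_TOL = 1e-9    # coordinates below this count as boundary, not interior
DEDUP_TOL = 1e-8         # max-norm tolerance for merging duplicate roots


@dataclass
class EquilibriumPoint:
    """A labeled equilibrium with residual and existence-condition report."""

    label: str                       # P0 | P1 | P2 | P3 | Pstar
    coords: np.ndarray
    residual: float
    exists: bool
    conditions: dict = field(default_factory=dict)   # name -> margin (>0 means holds)

    @property
    def x(self) -> float:
        return float(self.coords[0])

    @property
    def y(self) -> float:
        return float(self.coords[1])

    @property
    def z(self) -> float:
        return float(self.coords[2])


def _residual(coords: np.ndarray, p: NonDimParams) -> float:
    return float(np.max(np.abs(rhs_nondim(np.clip(coords, 0.0, None), p))))


def equilibrium_trivial_axial(p: NonDimParams) -> list[EquilibriumPoint]:
    """The extinction equilibrium P0 and the prey-only equilibrium P1 = (1/gamma, 0, 0)."""
    P0 = EquilibriumPoint("P0", np.zeros(3), 0.0, True)
    coords1 = np.array([1.0 / p.gamma, 0.0, 0.0])
    P1 = EquilibriumPoint(
        "P1", coords1, _residual(coords1, p), True,
        conditions={"gamma_positive": p.gamma},
    )
    return [P0, P1]


def _predator_nullcline_y(x: float, p: NonDimParams, y_max: float = 1e6) -> float | None:
    """Solve ``x / (1 + A1 x + A2 y + A3 x y) - delta - nu1 y = 0`` for y >= 0.

    The left-hand side is strictly decreasing in ``y`` (for nu1 > 0 or
    A2 + A3 x > 0), so at most one nonnegative root exists; returns None when
    the expression is already nonpositive at y = 0.
    """

    def q(y: float) -> float:
        B = 1.0 + p.A1 * x + p.A2 * y + p.A3 * x * y
        return x / B - p.delta - p.nu1 * y

    q0 = q(0.0)
    if q0 < 0.0:
        return None
    if q0 == 0.0:
        return 0.0
    hi = 1.0
    while q(hi) > 0.0:
        hi *= 2.0
        if hi > y_max:
            return None   # no finite root (degenerate parameters)
    return brentq(q, 0.0, hi, xtol=1e-14, rtol=1e-15)


def equilibrium_scavenger_free(
    p: NonDimParams, n_scan: int = 600
) -> list[EquilibriumPoint]:
    """All positive scavenger-free equilibria ``P2 = (xbar, ybar, 0)``.

    Eliminates ``y`` through the predator nullcline and bracket-scans the prey
    nullcline residual over ``x in (0, 1/gamma)``; each sign change is refined
    by Brent's method.  Returns an empty list when no positive root exists.
    """

    def F(x: float) -> float | None:
        y = _predator_nullcline_y(x, p)
        if y is None or y <= 0.0:
            return None
        B = 1.0 + p.A1 * x + p.A2 * y + p.A3 * x * y
        return (1.0 - p.gamma * x) - y / B

    x_hi = 1.0 / p.gamma
    xs = np.linspace(x_hi * 1e-6, x_hi * (1.0 - 1e-9), n_scan)
    vals = [F(x) for x in xs]
    points: list[EquilibriumPoint] = []
    for i in range(len(xs) - 1):
        a, b = vals[i], vals[i + 1]
        if a is None or b is None or a * b > 0.0:
            continue
        if a == 0.0 and i > 0:
            continue
        xr = brentq(lambda x: F(x), xs[i], xs[i + 1], xtol=1e-14, rtol=1e-15)
        yr = _predator_nullcline_y(xr, p)
        if yr is None or yr <= POSITIVITY_TOL:
            continue
        coords = np.array([xr, yr, 0.0])
        res = _residual(coords, p)
        if res < RESIDUAL_TOL and not any(
            np.max(np.abs(coords - q.coords)) < DEDUP_TOL for q in points
        ):
            points.append(EquilibriumPoint("P2", coords, res, True))
    points.sort(key=lambda q: q.x)
    return points


def scavenger_free_from_guess(
    p: NonDimParams, guess: Sequence[float]
) -> EquilibriumPoint | None:
    """Refine a scavenger-free equilibrium from a nearby ``(xbar, ybar)`` guess.

    Used for fast warm-started continuation of the P2 branch in a parameter.
    """

    def G(v):
        x, y = v
        B = 1.0 + p.A1 * x + p.A2 * y + p.A3 * x * y
        return [(1.0 - p.gamma * x) - y / B, x / B - p.delta - p.nu1 * y]

    sol = root(G, list(guess[:2]), method="hybr", tol=1e-13)
    if not sol.success:
        return None
    x, y = sol.x
    if x <= POSITIVITY_TOL or y <= POSITIVITY_TOL:
        return None
    coords = np.array([x, y, 0.0])
    res = _residual(coords, p)
    if res >= RESIDUAL_TOL:
        return None
    return EquilibriumPoint("P2", coords, res, True)


def equilibrium_predator_free(p: NonDimParams) -> EquilibriumPoint:
    """The predator-free equilibrium ``P3 = (xhat, 0, zhat)`` in closed form.

    ``xhat = (mu + nu2)/(nu2 gamma + alpha)``, ``zhat = (alpha - gamma mu)/
    (nu2 gamma + alpha)``; it exists (zhat > 0) iff ``alpha > gamma mu``:
    the scavenger's benefit from prey must beat its mortality at the prey's
    environmental limit.
    """
    denom = p.nu2 * p.gamma + p.alpha
    margin = p.alpha - p.gamma * p.mu
    if denom <= 0.0:
        return EquilibriumPoint(
            "P3", np.zeros(3), np.inf, False,
            conditions={"denominator_positive": denom, "alpha_gt_gamma_mu": margin},
        )
    xhat = (p.mu + p.nu2) / denom
    zhat = margin / denom
    exists = margin > 0.0
    coords = np.array([xhat, 0.0, max(zhat, 0.0)])
    res = _residual(coords, p) if exists else np.inf
    return EquilibriumPoint(
        "P3", coords, res, exists,
        conditions={"alpha_gt_gamma_mu": margin, "denominator_positive": denom},
    )


def _interior_system(p: NonDimParams):
    def G(v):
        return list(per_capita_nondim(v, p))

    return G


def interior_from_guess(
    p: NonDimParams, guess: Sequence[float]
) -> EquilibriumPoint | None:
    """Refine an interior equilibrium from a nearby guess (warm-started Newton).

    Solves the per-capita system ``f1 = g1 = h1 = 0`` and returns None unless
    all coordinates are strictly positive and the residual is below tolerance.
    """
    sol = root(_interior_system(p), list(guess), method="hybr", tol=1e-13)
    if not sol.success:
        return None
    coords = np.asarray(sol.x)
    if np.any(coords <= POSITIVITY_TOL):
        return None
    res = _residual(coords, p)
    if res >= RESIDUAL_TOL:
        return None
    return EquilibriumPoint("Pstar", coords, res, True)


def equilibrium_interior(
    p: NonDimParams, n_starts: int = 64, seed: int = 0
) -> list[EquilibriumPoint]:
    """All distinct strictly positive interior equilibria ``(x*, y*, z*)``.

    The three per-capita equations have no closed form, so roots are found by
    a multi-start Newton search from Latin-hypercube starts over
    ``[1e-3, 1/gamma] x [1e-3, 2] x [1e-3, 2]`` (seeded for reproducibility),
    deduplicated in max-norm.
    """
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    u = sampler.random(n_starts)
    lo = np.array([1e-3, 1e-3, 1e-3])
    hi = np.array([1.0 / p.gamma, 2.0, 2.0])
    starts = qmc.scale(u, lo, hi)
    points: list[EquilibriumPoint] = []
    for s in starts:
        pt = interior_from_guess(p, s)
        if pt is None:
            continue
        if not any(np.max(np.abs(pt.coords - q.coords)) < DEDUP_TOL for q in points):
            points.append(pt)
    points.sort(key=lambda q: q.x)
    return points


def all_equilibria(
    p: NonDimParams, n_starts: int = 64, seed: int = 0
) -> list[EquilibriumPoint]:
    """Every equilibrium of the model: P0, P1, all P2, P3, all interior points."""
    pts = equilibrium_trivial_axial(p)
    pts += equilibrium_scavenger_free(p)
    p3 = equilibrium_predator_free(p)
    pts.append(p3)
    pts += equilibrium_interior(p, n_starts=n_starts, seed=seed)
    return pts
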