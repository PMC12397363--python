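"""Uniform persistence and planar no-periodic-orbit (Dulac) checks.

Uniform persistence — every population staying bounded away from extinction —
is certified by an average Lyapunov function ``L = x^m1 y^m2 z^m3`` with
positive weights: it suffices that the logarithmic growth rate

    kappa = m1 (dx/dt)/x + m2 (dy/dt)/y + m3 (dz/dt)/z

is positive at every boundary equilibrium, which holds under

    (i)   gamma < alpha/mu  and  gamma < 1/delta - A1      (kappa(P1) > 0)
    (ii)  alpha xbar + beta ybar > mu                      (kappa(P2) > 0)
    (iii) nu2 + mu > delta (nu2 gamma + alpha)/(1 - delta A1)   (kappa(P3) > 0)

together with ``m1 > m2 delta + m3 mu`` so that ``kappa(P0) > 0``.  The
boundary flows must also have no planar limit cycles, which the
Bendixson-Dulac criterion with weight ``1/(xy)`` (resp. ``1/(xz)``) delivers
when the weighted divergence keeps one sign on the region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import NonDimParams, per_capita_nondim
from .equilibria import (
    EquilibriumPoint,
    equilibrium_predator_free,
    equilibrium_scavenger_free,
    equilibrium_trivial_axial,
)

__all__ = [
    "PersistenceWeights",
    "PersistenceReport",
    "DulacReport",
    "kappa_at_equilibrium",
    "uniform_persistence_check",
    "dulac_check_xy",
    "dulac_check_xz",
]


@dataclass(frozen=True)
class PersistenceWeights:
    """Positive weights of the average Lyapunov function ``x^m1 y^m2 z^m3``."""

    m1: float = 1.0
    m2: float = 1e-3
    m3: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.m1 > 0 and self.m2 > 0 and self.m3 > 0):
            raise ValueError("persistence weights must all be positive")


@dataclass
class PersistenceReport:
    kappa: dict                      # label -> kappa value at that boundary point
    conditions: dict                 # named margins of conditions (i)-(iii)
    verdict: str                     # persistent-by-criterion | criterion-fails | inapplicable
    weights: PersistenceWeights


@dataclass
class DulacReport:
    verdict: str                     # no-periodic-orbits-criterion-holds | inconclusive
    min_value: float
    max_value: float


def kappa_at_equilibrium(
    point: EquilibriumPoint, w: PersistenceWeights, p: NonDimParams
) -> float:
    """``kappa = m1 f1 + m2 g1 + m3 h1`` at a boundary equilibrium.

    The per-capita factors are finite even where a coordinate vanishes, so
    kappa is evaluated directly from them.  The criterion only concerns
    boundary points; an interior point raises.
    """
    if point.label == "Pstar" or np.all(point.coords > 0):
        raise ValueError("kappa criterion applies to boundary equilibria only")
    f1, g1, h1 = per_capita_nondim(point.coords, p)
    return float(w.m1 * f1 + w.m2 * g1 + w.m3 * h1)


def uniform_persistence_check(
    p: NonDimParams, w: PersistenceWeights | None = None
) -> PersistenceReport:
    """Evaluate conditions (i)-(iii) and the kappa signs at P0, P1, P2, P3.

    Verdict is ``persistent-by-criterion`` iff every condition holds strictly
    and kappa > 0 at every existing boundary equilibrium for the supplied
    weights; a failed criterion proves nothing about the flow itself.
    """
    if w is None:
        w = PersistenceWeights()
    conditions: dict[str, float] = {}
    inapplicable = False

    if p.mu > 0:
        conditions["i_gamma_lt_alpha_over_mu"] = p.alpha / p.mu - p.gamma
    else:
        inapplicable = True
    if p.delta > 0:
        conditions["i_gamma_lt_inv_delta_minus_A1"] = (1.0 / p.delta - p.A1) - p.gamma
    else:
        inapplicable = True

    p2s = equilibrium_scavenger_free(p)
    for i, pt in enumerate(p2s):
        conditions[f"ii_scavenger_invasion_P2_{i}"] = (
            p.alpha * pt.x + p.beta * pt.y - p.mu
        )

    one_minus_dA1 = 1.0 - p.delta * p.A1
    if one_minus_dA1 > 0:
        conditions["iii_predator_invasion"] = (p.nu2 + p.mu) - p.delta * (
            p.nu2 * p.gamma + p.alpha
        ) / one_minus_dA1
    else:
        inapplicable = True
        conditions["iii_inapplicable_one_minus_delta_A1"] = one_minus_dA1

    kappa: dict[str, float] = {}
    P0, P1 = equilibrium_trivial_axial(p)
    kappa["P0"] = kappa_at_equilibrium(P0, w, p)
    kappa["P1"] = kappa_at_equilibrium(P1, w, p)
    for i, pt in enumerate(p2s):
        kappa[f"P2_{i}" if len(p2s) > 1 else "P2"] = kappa_at_equilibrium(pt, w, p)
    p3 = equilibrium_predator_free(p)
    if p3.exists:
        kappa["P3"] = kappa_at_equilibrium(p3, w, p)

    if inapplicable:
        verdict = "inapplicable"
    elif all(m > 0 for m in conditions.values()) and all(k > 0 for k in kappa.values()):
        verdict = "persistent-by-criterion"
    else:
        verdict = "criterion-fails"
    return PersistenceReport(kappa=kappa, conditions=conditions, verdict=verdict, weights=w)


def _dulac_xy(x: np.ndarray, y: np.ndarray, p: NonDimParams) -> np.ndarray:
    B1 = 1.0 + p.A1 * x + p.A2 * y + p.A3 * x * y
    B2 = B1 * B1
    return -p.gamma / y - p.nu1 / x + (p.A1 + p.A3 * y) / B2 - (p.A2 + p.A3 * x) / B2


def dulac_check_xy(
    p: NonDimParams,
    x_range: tuple[float, float] = (1e-2, 2.0),
    y_range: tuple[float, float] = (1e-2, 2.0),
    n: int = 200,
) -> DulacReport:
    """Bendixson-Dulac check for the prey-predator subsystem on the xy-plane.

    Evaluates the divergence of the ``1/(xy)``-weighted planar field on a
    log-spaced grid; a strictly one-signed result rules out periodic orbits
    inside the grid region.  The grid must not touch the axes.
    """
    if x_range[0] <= 0 or y_range[0] <= 0:
        raise ValueError("Dulac grid must stay inside the open positive quadrant")
    xs = np.geomspace(*x_range, n)
    ys = np.geomspace(*y_range, n)
    X, Y = np.meshgrid(xs, ys)
    vals = _dulac_xy(X, Y, p)
    lo, hi = float(np.min(vals)), float(np.max(vals))
    one_signed = hi < 0.0 or lo > 0.0
    return DulacReport(
        verdict="no-periodic-orbits-criterion-holds" if one_signed else "inconclusive",
        min_value=lo,
        max_value=hi,
    )


def dulac_check_xz(
    p: NonDimParams,
    x_range: tuple[float, float] = (1e-2, 2.0),
    z_range: tuple[float, float] = (1e-2, 2.0),
    n: int = 200,
) -> DulacReport:
    """Dulac check for the prey-scavenger subsystem: the weighted divergence
    ``-gamma/z - nu2/x`` is negative everywhere in the open quadrant, so the
    criterion always holds for positive parameters."""
    if x_range[0] <= 0 or z_range[0] <= 0:
        raise ValueError("Dulac grid must stay inside the open positive quadrant")
    xs = np.geomspace(*x_range, n)
    zs = np.geomspace(*z_range, n)
    X, Z = np.meshgrid(xs, zs)
    vals = -p.gamma / Z - p.nu2 / X
    lo, hi = float(np.min(vals)), float(np.max(vals))
    one_signed = hi < 0.0 or lo > 0.0
    return DulacReport(
        verdict="no-periodic-orbits-criterion-holds" if one_signed else "inconclusive",
        min_value=lo,
        max_value=hi,
    )
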