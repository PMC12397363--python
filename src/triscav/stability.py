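"""Local stability analysis: Jacobian, characteristic coefficients, Routh-Hurwitz.

The Jacobian of the dimensionless model at a general state ``(x, y, z)`` has
closed-form entries (``B = 1 + A1 x + A2 y + A3 x y``; ``f1, g1, h1`` are the
per-capita factors, which vanish at an equilibrium with all coordinates
positive but contribute on the boundary)::

    J = [ x(-gamma + y(A1+A3 y)/B^2) + f1,   -x(1+A1 x)/B^2,            -x          ]
        [ y(1+A2 y)/B^2,                     y(-x(A2+A3 x)/B^2 - nu1) + g1,  0      ]
        [ alpha z,                           beta z,                    -nu2 z + h1 ]

The characteristic polynomial is ``lambda^3 + rho1 lambda^2 + rho2 lambda +
rho3`` with ``rho1 = -tr J``, ``rho2`` the sum of principal 2x2 minors and
``rho3 = -det J``; all eigenvalues have negative real part iff ``rho1 > 0``,
``rho3 > 0`` and ``rho1 rho2 - rho3 > 0`` (Routh-Hurwitz for a cubic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_model import NonDimParams, per_capita_nondim
from .equilibria import EquilibriumPoint

__all__ = [
    "StabilityReport",
    "RouthHurwitzVerdict",
    "jacobian",
    "characteristic_coefficients",
    "routh_hurwitz",
    "classify",
    "MARGINAL_BAND",
]

# Eigenvalues with |Re| below this band give no stability verdict; Hopf and
# transcritical location need honest sign changes, not misclassification noise.
MARGINAL_BAND = 1e-8


@dataclass
class RouthHurwitzVerdict:
    rho1_positive: bool
    rho3_positive: bool
    margin: float            # rho1*rho2 - rho3
    stable: bool


@dataclass
class StabilityReport:
    jacobian: np.ndarray
    rho: tuple[float, float, float]
    eigenvalues: np.ndarray
    routh_hurwitz: RouthHurwitzVerdict
    classification: str      # stable-node|stable-focus|saddle|unstable|center-candidate|marginal
    condition_report: dict = field(default_factory=dict)


def jacobian(
    state: Sequence[float], p: NonDimParams, *, equilibrium_form: bool = False
) -> np.ndarray:
    """Analytic Jacobian of the dimensionless right-hand side at ``state``.

    With ``equilibrium_form=True`` the per-capita diagonal additions
    ``f1, g1, h1`` are dropped: at an exact equilibrium they vanish anyway,
    and freezing them is what parameter-partial derivatives of the
    characteristic coefficients at a fixed equilibrium require.
    """
    x, y, z = state
    B = 1.0 + p.A1 * x + p.A2 * y + p.A3 * x * y
    B2 = B * B
    if equilibrium_form:
        f1 = g1 = h1 = 0.0
    else:
        f1, g1, h1 = per_capita_nondim(state, p)
    return np.array(
        [
            [
                x * (-p.gamma + y * (p.A1 + p.A3 * y) / B2) + f1,
                -x * (1.0 + p.A1 * x) / B2,
                -x,
            ],
            [
                y * (1.0 + p.A2 * y) / B2,
                y * (-x * (p.A2 + p.A3 * x) / B2 - p.nu1) + g1,
                0.0,
            ],
            [p.alpha * z, p.beta * z, -p.nu2 * z + h1],
        ]
    )


def characteristic_coefficients(J: np.ndarray) -> tuple[float, float, float]:
    """Coefficients ``(rho1, rho2, rho3)`` of ``lambda^3 + rho1 lambda^2 + rho2 lambda + rho3``.

    rho1 = -tr J; rho2 = sum of principal 2x2 minors; rho3 = -det J.
    """
    J = np.asarray(J, dtype=float)
    if J.shape != (3, 3):
        raise ValueError("J must be a real 3x3 matrix")
    rho1 = -np.trace(J)
    rho2 = (
        J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        + J[0, 0] * J[2, 2] - J[0, 2] * J[2, 0]
        + J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1]
    )
    rho3 = -np.linalg.det(J)
    return float(rho1), float(rho2), float(rho3)


def routh_hurwitz(rho: Sequence[float]) -> RouthHurwitzVerdict:
    """Routh-Hurwitz verdict for the cubic with coefficients ``rho``."""
    rho1, rho2, rho3 = (float(r) for r in rho)
    if not all(np.isfinite([rho1, rho2, rho3])):
        raise ValueError("characteristic coefficients must be finite")
    margin = rho1 * rho2 - rho3
    v1, v3 = rho1 > 0.0, rho3 > 0.0
    return RouthHurwitzVerdict(
        rho1_positive=v1,
        rho3_positive=v3,
        margin=margin,
        stable=v1 and v3 and margin > 0.0,
    )


def _classification(eigs: np.ndarray) -> str:
    re = eigs.real
    im = eigs.imag
    if np.any(np.abs(re) < MARGINAL_BAND):
        # a conjugate pair on the axis with the third eigenvalue stable is a
        # center candidate (potential Hopf); otherwise give no verdict
        pair_on_axis = np.sum(np.abs(re) < MARGINAL_BAND) == 2 and np.any(
            np.abs(im) > 0
        )
        return "center-candidate" if pair_on_axis else "marginal"
    if np.all(re < 0):
        return "stable-focus" if np.any(np.abs(im) > 0) else "stable-node"
    if np.all(re > 0):
        return "unstable"
    return "saddle"


def classify(point: EquilibriumPoint, p: NonDimParams) -> StabilityReport:
    """Full stability report for an equilibrium, including the closed-form
    inequality conditions the label admits.

    For P1 the local-stability condition is ``gamma > alpha/mu`` and
    ``gamma > 1/delta - A1``; for P2 it is ``T1 < 0``, ``D1 > 0`` and
    ``a33 = alpha xbar + beta ybar - mu < 0``; for P3 the planar pair is
    always contracting (``T2 < 0``, ``D2 > 0``) and stability hinges on
    ``b22 = -delta + xhat/(1 + A1 xhat) < 0``, i.e.
    ``nu2 + mu < delta (nu2 gamma + alpha)/(1 - delta A1)``; the interior
    point uses Routh-Hurwitz on the characteristic coefficients.
    """
    if not point.exists:
        raise ValueError(f"equilibrium {point.label} does not exist for these parameters")
    J = jacobian(point.coords, p)
    rho = characteristic_coefficients(J)
    eigs = np.linalg.eigvals(J)
    rh = routh_hurwitz(rho)
    cond: dict[str, float] = {}
    x, y, z = point.coords
    if point.label == "P1":
        if p.mu > 0:
            cond["gamma_minus_alpha_over_mu"] = p.gamma - p.alpha / p.mu
        if p.delta > 0:
            cond["gamma_minus_inv_delta_minus_A1"] = p.gamma - (1.0 / p.delta - p.A1)
    elif point.label == "P2":
        T1 = J[0, 0] + J[1, 1]
        D1 = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        a33 = p.alpha * x + p.beta * y - p.mu
        cond["T1"] = T1
        cond["D1"] = D1
        cond["a33"] = a33
    elif point.label == "P3":
        T2 = J[0, 0] + J[2, 2]
        D2 = J[0, 0] * J[2, 2] - J[2, 0] * J[0, 2]
        b22 = -p.delta + x / (1.0 + p.A1 * x)
        cond["T2"] = T2
        cond["D2"] = D2
        cond["b22"] = b22
        one_minus_dA1 = 1.0 - p.delta * p.A1
        cond["one_minus_delta_A1"] = one_minus_dA1
        if one_minus_dA1 > 0:
            # nu2 + mu < delta(nu2 gamma + alpha)/(1 - delta A1) <=> b22 < 0
            cond["predator_free_stability_margin"] = (
                p.delta * (p.nu2 * p.gamma + p.alpha) / one_minus_dA1
                - (p.nu2 + p.mu)
            )
    elif point.label == "Pstar":
        cond["rho1"] = rho[0]
        cond["rho3"] = rho[2]
        cond["rh_margin"] = rh.margin
    return StabilityReport(
        jacobian=J,
        rho=rho,
        eigenvalues=eigs,
        routh_hurwitz=rh,
        classification=_classification(eigs),
        condition_report=cond,
    )
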