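"""Bifurcation location and orbit-based diagnostics.

Two codim-1 bifurcations organize the dynamics of the model:

* **Transcritical (branch point)** on the scavenger-free branch ``P2``: the
  z-direction eigenvalue ``a33 = alpha xbar + beta ybar - mu`` crosses zero,
  exchanging stability between ``P2`` and a nearby interior equilibrium
  (scavenger invasion threshold).  Sotomayor's conditions ``Delta1 = 0``,
  ``Delta2 != 0``, ``Delta3 != 0`` certify the transcritical type.

* **Hopf** on the interior branch: located through Liu's criterion, which
  replaces the eigenvalue crossing by the scalar root
  ``phi = rho1 rho2 - rho3 = 0`` with ``rho1 > 0`` and ``rho3 > 0`` (for a
  cubic these are equivalent), plus transversality ``d phi/d p != 0``.  The
  criticality is the sign of the first Lyapunov coefficient, computed by the
  standard normal-form projection onto the center eigenspace.

Orbit-based diagnostics classify the post-transient attractor from the local
maxima of ``x(t)``: an equilibrium (sub-tolerance amplitude), a period-n
cycle (n distinct maxima repeating in order), or chaos (maxima clusters
overflow / non-repeating), optionally corroborated by a Benettin
two-trajectory largest-Lyapunov-exponent estimate.  Scanning a parameter grid
yields the familiar bifurcation diagrams including the period-doubling
cascade to chaos.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .core_model import NonDimParams, integrate_orbit, rhs_nondim
from .equilibria import (
    EquilibriumPoint,
    equilibrium_interior,
    equilibrium_scavenger_free,
    interior_from_guess,
    scavenger_free_from_guess,
)
from .stability import characteristic_coefficients, jacobian

__all__ = [
    "BifurcationEvent",
    "OrbitSummary",
    "P2Branch",
    "InteriorBranch",
    "locate_transcritical",
    "sotomayor_diagnostics",
    "hopf_phi",
    "locate_hopf",
    "first_lyapunov_sign",
    "orbit_classify",
    "bifurcation_diagram",
    "largest_lyapunov_exponent",
    "DEFAULT_X0",
]

# Default interior initial condition for demo orbits, near the coexistence
# equilibrium of the reference parameter set.
DEFAULT_X0 = (0.4, 0.8, 0.02)

_EIG_ZERO_TOL = 1e-8


@dataclass
class BifurcationEvent:
    kind: str                    # "transcritical" | "hopf"
    param: str
    critical_value: float
    equilibrium: np.ndarray
    diagnostics: dict = field(default_factory=dict)


@dataclass
class OrbitSummary:
    attractor_type: str          # "equilibrium" | "periodic-n" | "chaotic"
    n_distinct_maxima: int
    maxima_samples: np.ndarray
    transient_used: float
    classification_tolerance: float
    amplitude: float = 0.0
    lle: float | None = None
    final_state: np.ndarray | None = None

    @property
    def period(self) -> int | None:
        if self.attractor_type.startswith("periodic-"):
            return int(self.attractor_type.split("-")[1])
        return None


class P2Branch:
    """Warm-started continuation of the scavenger-free equilibrium in one parameter."""

    def __init__(self, p: NonDimParams, param: str, value0: float):
        self.p = p
        self.param = param
        pts = equilibrium_scavenger_free(p.replace(**{param: value0}))
        if not pts:
            raise ValueError(
                f"no scavenger-free equilibrium at {param}={value0}; cannot start branch"
            )
        # continue the branch through the smallest-x root (the one the
        # reference parameter set follows); callers may reseed via `guess`
        self._last = pts[0].coords[:2].copy()

    def point(self, value: float) -> EquilibriumPoint:
        pv = self.p.replace(**{self.param: value})
        pt = scavenger_free_from_guess(pv, self._last)
        if pt is None:
            pts = equilibrium_scavenger_free(pv)
            if not pts:
                raise ValueError(f"P2 branch lost at {self.param}={value}")
            pt = min(pts, key=lambda q: abs(q.x - self._last[0]))
        self._last = pt.coords[:2].copy()
        return pt

    def a33(self, value: float) -> float:
        pv = self.p.replace(**{self.param: value})
        pt = self.point(value)
        return pv.alpha * pt.x + pv.beta * pt.y - pv.mu


class InteriorBranch:
    """Warm-started continuation of the interior equilibrium in one parameter."""

    def __init__(
        self,
        p: NonDimParams,
        param: str,
        value0: float,
        guess: Sequence[float] | None = None,
        seed: int = 0,
    ):
        self.p = p
        self.param = param
        p0 = p.replace(**{param: value0})
        if guess is not None:
            pt = interior_from_guess(p0, guess)
            pts = [pt] if pt is not None else []
        else:
            pts = equilibrium_interior(p0, seed=seed)
        if not pts:
            raise ValueError(
                f"no interior equilibrium at {param}={value0}; cannot start branch"
            )
        self._last = pts[0].coords.copy()

    def point(self, value: float) -> EquilibriumPoint:
        pv = self.p.replace(**{self.param: value})
        pt = interior_from_guess(pv, self._last)
        if pt is None:
            pts = equilibrium_interior(pv)
            if not pts:
                raise ValueError(f"interior branch lost at {self.param}={value}")
            pt = min(pts, key=lambda q: float(np.max(np.abs(q.coords - self._last))))
        self._last = pt.coords.copy()
        return pt

    def phi(self, value: float) -> tuple[float, float, float, float]:
        """Liu function ``phi = rho1 rho2 - rho3`` and the rho's at this value."""
        pv = self.p.replace(**{self.param: value})
        pt = self.point(value)
        rho1, rho2, rho3 = characteristic_coefficients(jacobian(pt.coords, pv))
        return rho1 * rho2 - rho3, rho1, rho2, rho3


def locate_transcritical(
    p: NonDimParams, param: str, bracket: tuple[float, float]
) -> BifurcationEvent:
    """Root of ``a33(param) = 0`` along the continued P2 branch.

    Raises if ``a33`` does not change sign over the bracket.
    """
    lo, hi = bracket
    branch = P2Branch(p, param, lo)
    f_lo, f_hi = branch.a33(lo), branch.a33(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"a33 does not change sign over [{lo}, {hi}]: "
            f"a33({lo})={f_lo:.6g}, a33({hi})={f_hi:.6g}"
        )
    crit = brentq(branch.a33, lo, hi, xtol=1e-13, rtol=1e-14)
    pt = branch.point(crit)
    pv = p.replace(**{param: crit})
    a33 = pv.alpha * pt.x + pv.beta * pt.y - pv.mu
    event = BifurcationEvent(
        kind="transcritical",
        param=param,
        critical_value=float(crit),
        equilibrium=pt.coords.copy(),
        diagnostics={"a33": a33},
    )
    event.diagnostics.update(sotomayor_diagnostics(event, p))
    return event


def sotomayor_diagnostics(event: BifurcationEvent, p: NonDimParams) -> dict:
    """Sotomayor quantities at a transcritical event on the P2 branch.

    ``U`` is the right null vector of ``J(P2)`` at the critical parameter
    (unit norm, third component positive) and ``W = (0, 0, 1)`` the left one.
    ``Delta1 = 0`` structurally (the parameter enters only through the z
    equation, which vanishes at z = 0); ``Delta2 = ybar u3`` and
    ``Delta3 = -2 nu2 u3^2 + 2 beta u2 u3 + 2 alpha u1 u3``.  A transcritical
    bifurcation requires ``Delta1 = 0``, ``Delta2 != 0``, ``Delta3 != 0``.
    """
    if event.kind != "transcritical":
        raise ValueError("Sotomayor diagnostics apply to transcritical events")
    pv = p.replace(**{event.param: event.critical_value})
    coords = event.equilibrium
    J = jacobian(coords, pv)
    eigvals, eigvecs = np.linalg.eig(J)
    order = np.argsort(np.abs(eigvals))
    if np.abs(eigvals[order[0]]) > _EIG_ZERO_TOL:
        raise ValueError("no zero eigenvalue at the reported critical parameter")
    if np.abs(eigvals[order[1]]) < _EIG_ZERO_TOL:
        return {"degenerate": True}
    U = np.real(eigvecs[:, order[0]])
    U = U / np.linalg.norm(U)
    if U[2] < 0:
        U = -U
    W = np.array([0.0, 0.0, 1.0])
    ybar = coords[1]
    u1, u2, u3 = U
    delta2 = ybar * u3
    delta3 = -2.0 * pv.nu2 * u3 ** 2 + 2.0 * pv.beta * u2 * u3 + 2.0 * pv.alpha * u1 * u3
    return {
        "Delta1": 0.0,
        "Delta2": float(delta2),
        "Delta3": float(delta3),
        "U": U,
        "W": W,
        "is_transcritical": delta2 != 0.0 and delta3 != 0.0,
        "degenerate": False,
    }


def hopf_phi(
    p: NonDimParams,
    equilibrium: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[float, float, float, float]:
    """Liu function ``phi = rho1 rho2 - rho3`` at the interior equilibrium.

    The equilibrium is solved fresh (or refined from ``equilibrium`` if
    given); the Jacobian route is used, not any expanded symbolic formula.
    Returns ``(phi, rho1, rho2, rho3)``.
    """
    if equilibrium is not None:
        pt = interior_from_guess(p, equilibrium)
        if pt is None:
            raise ValueError("no interior equilibrium near the supplied guess")
    else:
        pts = equilibrium_interior(p, seed=seed)
        if not pts:
            raise ValueError("no interior equilibrium for these parameters")
        pt = pts[0]
    rho1, rho2, rho3 = characteristic_coefficients(jacobian(pt.coords, p))
    return rho1 * rho2 - rho3, rho1, rho2, rho3


def locate_hopf(
    p: NonDimParams,
    param: str,
    bracket: tuple[float, float],
    guess: Sequence[float] | None = None,
    seed: int = 0,
) -> BifurcationEvent:
    """Hopf point as the root of ``phi(param) = 0`` on the interior branch.

    Checks ``rho1 > 0`` and ``rho3 > 0`` at the root (otherwise the zero of
    ``phi`` is not a Hopf point) and estimates the transversality derivative
    ``d phi / d param`` by central differences along the branch.
    """
    lo, hi = bracket
    branch = InteriorBranch(p, param, lo, guess=guess, seed=seed)

    def phi(v: float) -> float:
        return branch.phi(v)[0]

    f_lo, f_hi = phi(lo), phi(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"phi does not change sign over [{lo}, {hi}]: "
            f"phi({lo})={f_lo:.6g}, phi({hi})={f_hi:.6g}"
        )
    crit = brentq(phi, lo, hi, xtol=1e-13, rtol=1e-14)
    phi_c, rho1, rho2, rho3 = branch.phi(crit)
    pt = branch.point(crit)
    if not (rho1 > 0 and rho3 > 0):
        raise ValueError(
            f"phi root at {param}={crit:.6g} has rho1={rho1:.4g}, rho3={rho3:.4g}; "
            "not a Hopf point (real-eigenvalue fold)"
        )
    h = 1e-5 * max(1.0, abs(crit))
    # Transversality diagnostic as the analysis defines it: the explicit
    # partial of phi in the parameter with the equilibrium frozen, using the
    # equilibrium-form Jacobian (per-capita diagonal terms identically zero
    # on the branch, so they are not re-evaluated off it).
    def phi_frozen(v: float) -> float:
        pv = p.replace(**{param: v})
        r1, r2, r3 = characteristic_coefficients(
            jacobian(pt.coords, pv, equilibrium_form=True)
        )
        return r1 * r2 - r3

    dphi = (phi_frozen(crit + h) - phi_frozen(crit - h)) / (2.0 * h)
    dphi_branch = (phi(crit + h) - phi(crit - h)) / (2.0 * h)
    event = BifurcationEvent(
        kind="hopf",
        param=param,
        critical_value=float(crit),
        equilibrium=pt.coords.copy(),
        diagnostics={
            "phi": phi_c,
            "dphi_dparam": float(dphi),
            "dphi_dparam_branch": float(dphi_branch),
            "rho1": rho1,
            "rho2": rho2,
            "rho3": rho3,
        },
    )
    return event


# ---------------------------------------------------------------------------
# Hopf criticality: first Lyapunov coefficient by normal-form projection
# ---------------------------------------------------------------------------

def _directional_d2(F, x0, u, v, h=1e-3):
    """Symmetric bilinear form B(u, v) = D^2 F(x0)[u, v] by central differences.

    Supports complex direction vectors (the field is rational, hence entire
    in each coordinate, so complex evaluation is exact differentiation fuel).
    """
    return (
        F(x0 + h * (u + v)) - F(x0 + h * (u - v))
        - F(x0 - h * (u - v)) + F(x0 - h * (u + v))
    ) / (4.0 * h * h)


def _directional_d3(F, x0, u, v, w, h=1e-2):
    """Trilinear form C(u, v, w) = D^3 F(x0)[u, v, w] by central differences."""
    out = 0.0
    for su in (1.0, -1.0):
        for sv in (1.0, -1.0):
            for sw in (1.0, -1.0):
                out = out + su * sv * sw * F(x0 + h * (su * u + sv * v + sw * w))
    return out / (8.0 * h ** 3)


def _rhs_complex(p: NonDimParams):
    def F(u):
        x, y, z = u
        B = 1.0 + p.A1 * x + p.A2 * y + p.A3 * x * y
        return np.array(
            [
                x * ((1.0 - p.gamma * x) - y / B - z),
                y * (x / B - p.delta - p.nu1 * y),
                z * (p.alpha * x + p.beta * y - p.mu - p.nu2 * z),
            ]
        )

    return F


def first_lyapunov_sign(event: BifurcationEvent, p: NonDimParams) -> tuple[int, float]:
    """Sign of the first Lyapunov coefficient at a Hopf event.

    Uses the center-manifold projection formula

        l1 = Re[ <p, C(q,q,qb)> - 2 <p, B(q, A^{-1} B(q,qb))>
                 + <p, B(qb, (2 i w I - A)^{-1} B(q,q))> ] / (2 w)

    with ``A q = i w q``, ``A^T pvec = -i w pvec``, ``<pvec, q> = 1``.  Only
    the sign is contractually meaningful (the magnitude depends on eigenvector
    scaling conventions); negative means supercritical (a stable small cycle
    is born).  Returns ``(sign, l1)``.
    """
    if event.kind != "hopf":
        raise ValueError("first Lyapunov coefficient applies to Hopf events")
    pv = p.replace(**{event.param: event.critical_value})
    x0 = event.equilibrium.astype(complex)
    A = jacobian(event.equilibrium, pv)
    eigvals, eigvecs = np.linalg.eig(A)
    cand = [i for i in range(3) if eigvals[i].imag > 0]
    if not cand:
        raise ValueError("Jacobian has no eigenvalue pair with positive imaginary part")
    i_q = min(cand, key=lambda i: abs(eigvals[i].real))
    if abs(eigvals[i_q].real) > 1e-6:
        raise ValueError("eigenvalue pair is not on the imaginary axis; not a Hopf point")
    omega = eigvals[i_q].imag
    q = eigvecs[:, i_q]
    eigvalsT, eigvecsT = np.linalg.eig(A.T)
    i_p = int(np.argmin(np.abs(eigvalsT - (-1j * omega))))
    pvec = eigvecsT[:, i_p]
    # normalize <p, q> = conj(p) . q = 1 (vdot conjugates its first argument,
    # so divide by the conjugate of the inner product)
    pvec = pvec / np.conj(np.vdot(pvec, q))
    F = _rhs_complex(pv)

    def B(u, v):
        return _directional_d2(F, x0, u, v)

    qb = np.conj(q)
    c1 = np.vdot(pvec, _directional_d3(F, x0, q, q, qb))
    s = np.linalg.solve(A, B(q, qb))
    c2 = -2.0 * np.vdot(pvec, B(q, s))
    M = 2j * omega * np.eye(3) - A
    r = np.linalg.solve(M, B(q, q))
    c3 = np.vdot(pvec, B(qb, r))
    l1 = float(np.real(c1 + c2 + c3) / (2.0 * omega))
    return (-1 if l1 < 0 else (1 if l1 > 0 else 0)), l1


# ---------------------------------------------------------------------------
# Orbit-based attractor classification
# ---------------------------------------------------------------------------

def _local_maxima(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Values of interior local maxima of the sampled series, refined by a
    quadratic fit through each peak's three samples."""
    core = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])
    idx = np.flatnonzero(core) + 1
    if idx.size == 0:
        return np.array([])
    xm = x[idx]
    a = x[idx - 1]
    b = x[idx]
    c = x[idx + 1]
    denom = a - 2 * b + c
    mask = denom < 0
    # vertex value of the parabola through the three points
    refined = b - 0.125 * (a - c) ** 2 / np.where(mask, denom, -1.0)
    return np.where(mask, refined, xm)


def _cluster_1d(values: np.ndarray, tol: float) -> tuple[np.ndarray, int]:
    """Assign 1-d values to clusters separated by gaps > tol.

    Returns (labels aligned with `values`, number of clusters).
    """
    order = np.argsort(values)
    sv = values[order]
    labels_sorted = np.zeros(values.size, dtype=int)
    lab = 0
    for i in range(1, sv.size):
        if sv[i] - sv[i - 1] > tol:
            lab += 1
        labels_sorted[i] = lab
    labels = np.empty(values.size, dtype=int)
    labels[order] = labels_sorted
    return labels, lab + 1


def orbit_classify(
    p: NonDimParams,
    x0: Sequence[float] = DEFAULT_X0,
    transient: float = 3000.0,
    sample_window: float = 2000.0,
    tol: float = 1e-3,
    n_max: int = 16,
    dt: float = 0.05,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    compute_lle: bool = False,
) -> OrbitSummary:
    """Classify the post-transient attractor from the local maxima of x(t).

    Integrates through ``transient``, then samples ``sample_window`` time
    units with step ``dt``; clusters the x-maxima with absolute tolerance
    ``tol``.  Sub-tolerance amplitude -> equilibrium; n <= n_max clusters
    repeating cyclically -> periodic-n; otherwise -> chaotic.
    """
    tr = integrate_orbit(p, x0, transient, n_samples=64, rtol=rtol, atol=atol)
    if not np.all(np.isfinite(tr.states)) or np.max(tr.states) > 1e6:
        raise RuntimeError("trajectory appears unbounded during the transient")
    xT = tr.states[-1]
    n = int(sample_window / dt) + 1
    orb = integrate_orbit(
        p, xT, transient + sample_window, t_start=transient,
        n_samples=n, rtol=rtol, atol=atol,
    )
    if not np.all(np.isfinite(orb.states)) or np.max(orb.states) > 1e6:
        raise RuntimeError("trajectory appears unbounded over the sampling window")
    x = orb.x
    amplitude = float(np.max(x) - np.min(x))
    if amplitude < tol:
        return OrbitSummary(
            attractor_type="equilibrium",
            n_distinct_maxima=0,
            maxima_samples=np.array([]),
            transient_used=transient,
            classification_tolerance=tol,
            amplitude=amplitude,
            final_state=orb.states[-1].copy(),
        )
    maxima = _local_maxima(orb.t, x)
    if maxima.size == 0:
        # oscillation slower than the window; treat as period-1 candidate
        maxima = np.array([np.max(x)])
    labels, n_clusters = _cluster_1d(maxima, tol)
    attractor = f"periodic-{n_clusters}"
    if n_clusters > n_max:
        attractor = "chaotic"
    elif n_clusters > 1 and maxima.size >= 2 * n_clusters:
        # a true period-n orbit visits its n maxima in a fixed cyclic order
        seq = labels
        if np.any(seq[: -n_clusters] != seq[n_clusters:]):
            attractor = "chaotic"
    lle = None
    if compute_lle:
        lle = largest_lyapunov_exponent(p, xT, t_total=min(sample_window, 1000.0))
    return OrbitSummary(
        attractor_type=attractor,
        n_distinct_maxima=int(n_clusters) if attractor != "chaotic" else int(n_clusters),
        maxima_samples=maxima,
        transient_used=transient,
        classification_tolerance=tol,
        amplitude=amplitude,
        lle=lle,
        final_state=orb.states[-1].copy(),
    )


def largest_lyapunov_exponent(
    p: NonDimParams,
    x0: Sequence[float],
    t_total: float = 1000.0,
    renorm_dt: float = 1.0,
    d0: float = 1e-8,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> float:
    """Benettin two-trajectory estimate of the largest Lyapunov exponent.

    Runs a fiducial and a perturbed orbit, renormalizing the separation back
    to ``d0`` every ``renorm_dt`` time units; the mean log stretching rate
    estimates the exponent (> 0 indicates chaos).
    """
    rng_dir = np.ones(3) / np.sqrt(3.0)
    a = np.asarray(x0, dtype=float)
    b = np.clip(a + d0 * rng_dir, 0.0, None)
    n_steps = int(t_total / renorm_dt)
    logs = []
    for _ in range(n_steps):
        ta = integrate_orbit(p, a, renorm_dt, n_samples=2, rtol=rtol, atol=atol)
        tb = integrate_orbit(p, b, renorm_dt, n_samples=2, rtol=rtol, atol=atol)
        a = ta.states[-1]
        b = tb.states[-1]
        d = np.linalg.norm(b - a)
        if d == 0.0:
            b = np.clip(a + d0 * rng_dir, 0.0, None)
            continue
        logs.append(np.log(d / d0))
        b = a + (b - a) * (d0 / d)
    return float(np.sum(logs) / (len(logs) * renorm_dt)) if logs else 0.0


def bifurcation_diagram(
    p: NonDimParams,
    param: str,
    grid: Sequence[float],
    x0: Sequence[float] = DEFAULT_X0,
    transient: float = 3000.0,
    sample_window: float = 2000.0,
    tol: float = 1e-3,
    warm_start: bool = False,
    **orbit_kwargs,
):
    """Attractor scan over a parameter grid.

    Returns a pandas DataFrame with one row per grid value: the attractor
    type, the number of distinct x-maxima, and the maxima themselves
    (semicolon-joined).  Per-point failures are recorded and the scan
    continues.  With ``warm_start`` the final state of each orbit seeds the
    next grid point (off by default: every point then starts from ``x0``).
    """
    import pandas as pd

    rows = []
    start = np.asarray(x0, dtype=float)
    for v in grid:
        pv = p.replace(**{param: float(v)})
        try:
            summary = orbit_classify(
                pv, start, transient=transient, sample_window=sample_window,
                tol=tol, **orbit_kwargs,
            )
            rows.append(
                {
                    "param_value": float(v),
                    "attractor_type": summary.attractor_type,
                    "n_maxima": summary.n_distinct_maxima,
                    "maxima": ";".join(f"{m:.6f}" for m in summary.maxima_samples[:64]),
                    "error": "",
                }
            )
            if warm_start and summary.final_state is not None:
                start = summary.final_state
        except Exception as exc:  # per-point failure: record and continue
            rows.append(
                {
                    "param_value": float(v),
                    "attractor_type": "error",
                    "n_maxima": -1,
                    "maxima": "",
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows)
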