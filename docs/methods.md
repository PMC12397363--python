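# Methods

## Model and assumptions

The package implements a three-species food web: logistic prey, a predator
feeding through a Crowley–Martin functional response, and a scavenger that
both hunts live prey and consumes naturally dead predators. The carcass
pathway is assumed one-way — the scavenger's gain `βyz` imposes no loss on
the live predator equation — which is the defining structural assumption of
the model (think whelks scavenging dead fish while drilling live bivalves).
Harvesting of predator and scavenger is quadratic in the stock (`qEX²`):
catch per unit effort grows with crowding, a standard alternative to linear
and Michaelis–Menten harvesting that keeps the control problem strictly
concave in effort.

Both parameterizations are first-class. The dimensional model
`(X₁, X₂, X₃)` with sixteen ecological parameters is used for the
harvesting-economics problem (where efforts, prices and costs have units);
the dimensionless model `(x, y, z)` with ten parameters is used for the
dynamical analysis. The mapping is the substitution `x = (c/r)X₁`,
`y = (a/r)X₂`, `z = (b/r)X₃`, `t = rT`. One consequence worth stating
explicitly: the harvesting groups come out as `ν₁ = q₁E₁/a` (predator) and
`ν₂ = q₂E₂/b` (scavenger), i.e. each divides by its own population's
rescaling constant. This is the unique mapping under which the two
right-hand sides agree, and a property test asserts that agreement at
1e-10 relative tolerance on random parameter draws.

Structural facts used throughout: each right-hand side carries its own
state factor, so the coordinate planes are invariant and the nonnegative
octant is forward-invariant; the sum `x + y + z/α` is eventually bounded by
`(1+M)²/(4Mγ)`, `M = min(δ, μ)`, whenever `β² < 4αν₁ν₂` (a sufficient
condition only — the reference parameter set violates it and is still
bounded in practice).

## Equilibria

`P0 = (0,0,0)` and `P1 = (1/γ, 0, 0)` are explicit. `P3 = (x̂, 0, ẑ)` is the
closed form `x̂ = (μ+ν₂)/(ν₂γ+α)`, `ẑ = (α−γμ)/(ν₂γ+α)`, existing iff
`α > γμ` (strict).

The scavenger-free state `P2 = (x̄, ȳ, 0)` solves the nullcline pair
`(1−γx̄) = ȳ/B`, `x̄/B = δ + ν₁ȳ` with `B = 1 + A₁x̄ + A₂ȳ + A₃x̄ȳ`. The
second equation has a unique nonnegative root `ȳ(x̄)` (its left side is
strictly decreasing in `ȳ`), so the system reduces to one scalar equation
on `x̄ ∈ (0, 1/γ)`. The solver bracket-scans that interval (600 points) and
refines each sign change with Brent's method; this resolves the 0/1/2/3-root
regimes robustly and every reported root is re-verified to residual < 1e-10.

The interior state has no closed form. It is found by multi-start Newton
(`scipy.optimize.root`, hybr) on the per-capita system `f₁ = g₁ = h₁ = 0`,
started from a seeded Latin-hypercube sample (default 64 starts) over
`[1e-3, 1/γ] × [1e-3, 2] × [1e-3, 2]`, deduplicated at 1e-8 in max-norm;
coordinates below 1e-9 are classified as boundary, not interior. Solving
the per-capita system (rather than the raw right-hand side) excludes the
boundary equilibria from the search automatically. A brute-force grid
oracle (sign changes of all three components over a coarse lattice) checks
completeness in the tests.

## Stability

The Jacobian is analytic, including the per-capita diagonal additions that
vanish at interior equilibria but matter on the boundary; a finite-difference
test pins it at 1e-6. Characteristic coefficients are `ρ₁ = −tr J`,
`ρ₂ = Σ` principal minors, `ρ₃ = −det J`; the Routh–Hurwitz conditions for a
cubic (`ρ₁ > 0`, `ρ₃ > 0`, `ρ₁ρ₂ − ρ₃ > 0`) give the stability verdict, and
the named closed-form inequality margins for each boundary equilibrium are
reported alongside the eigenvalues. Eigenvalues within 1e-8 of the
imaginary axis yield a "marginal"/"center-candidate" classification rather
than a verdict — bifurcation location needs honest sign changes, not
misclassification noise. One transcription note: the published display of
the `P2` block writes an `A₂₄` in the `a₂₁` denominator; the general
Jacobian makes clear this is `A₂`, and the implementation follows the
general form.

A caution on the prey-only state: LAS of `P1` needs *both* `γ > α/μ` and
`γ > 1/δ − A₁`. At the reference parameter set the second fails
(`0.9 < 3.89`), so `P1` is a saddle — the eigenvalue `−δ + 1/(γ+A₁) = +0.74`
is positive. `classify()` reports both margins and the eigenvalue verdict,
which agree by construction.

## Bifurcations

**Transcritical (scavenger invasion).** Along the `P2` branch the
z-direction eigenvalue is exactly `a₃₃ = αx̄ + βȳ − μ`. The locator
continues the branch in the chosen parameter (warm-started Newton from the
previous solution) and Brent-roots `a₃₃ = 0` to 1e-13. At the root the
Sotomayor quantities are computed from the right/left null vectors `U`
(unit norm, third component positive) and `W = (0,0,1)`: `Δ₁ = 0` holds
structurally (the bifurcation parameter enters only the z-equation, which
vanishes at `z = 0`), `Δ₂ = ȳu₃` and
`Δ₃ = −2ν₂u₃² + 2βu₂u₃ + 2αu₁u₃`; both nonzero certifies the transcritical
type.

**Hopf via Liu's criterion.** For a cubic characteristic polynomial, a
conjugate pair crossing the imaginary axis is equivalent to
`φ = ρ₁ρ₂ − ρ₃ = 0` with `ρ₁, ρ₃ > 0`, which replaces eigenvalue tracking
by a scalar root-find. `φ` is evaluated from the Jacobian at a freshly
solved interior equilibrium at every parameter value (warm-started
continuation), and the root is located by Brent to 1e-13. If `ρ₁` or `ρ₃`
is nonpositive at the root the event is rejected as a real-eigenvalue fold.

The reported transversality diagnostic `dφ/dp` is the *explicit* parameter
partial: the equilibrium is frozen and the Jacobian taken in equilibrium
form (per-capita diagonal terms identically zero on the branch, hence not
re-evaluated off it), differentiated centrally with step `1e-5·max(1,|p|)`.
This matches the analytic expansion
`∂φ/∂ν₁ = yρ₂ − y(c₁₁+c₃₃)ρ₁ + y(c₃₁c₁₃ − c₁₁c₃₃)` of the Liu function.
The total derivative along the branch (equilibrium moving with the
parameter) is stored separately as `dphi_dparam_branch`; both being nonzero
is what a simple crossing requires, and finite differences generalize the
diagnostic to β, A₁, A₂, A₃ where no symbolic expansion is printed.

**Criticality.** The first Lyapunov coefficient is computed by the standard
normal-form projection: with `Aq = iωq`, `Aᵀp = −iωp`, `⟨p,q⟩ = 1`,

    l₁ = Re[⟨p, C(q,q,q̄)⟩ − 2⟨p, B(q, A⁻¹B(q,q̄))⟩
            + ⟨p, B(q̄, (2iωI−A)⁻¹B(q,q))⟩] / (2ω).

The bilinear/trilinear forms `B`, `C` are exact mixed directional
derivatives of the vector field, evaluated by central differences with
complex direction vectors (the field is rational, so complex evaluation is
legitimate; steps 1e-3 and 1e-2 balance truncation against roundoff). Only
the **sign** of `l₁` is contractually meaningful — the magnitude depends on
eigenvector scaling conventions and is deliberately not compared against
any continuation software's normal-form coefficients. The pipeline is
validated on the planar Hopf normal form embedded in 3-d (sign recovered
exactly) and corroborated at the reference Hopf point by the existence of a
small-amplitude attracting cycle just on the unstable side.

**Orbit classification.** Attractors are classified from the local maxima
of `x(t)` after a transient: amplitude below tolerance → equilibrium;
otherwise maxima are refined by a three-point parabolic fit, clustered by
sorted gaps larger than the tolerance (default 1e-3), and a cluster count
`n ≤ 16` whose label sequence repeats with period `n` → periodic-n; cluster
overflow or a non-repeating sequence → chaotic. Defaults — transient 3000,
window 2000 time units, sampling step 0.05 — were chosen to resolve the
period-8 window near ν₁ = 0.032, the narrowest feature of the cascade. An
optional Benettin two-trajectory largest-Lyapunov-exponent estimate
(renormalization every 1 time unit) corroborates the chaos label. Scans
start every grid point from the same initial condition by default
(warm-starting is available but off, so hysteresis cannot silently shape a
diagram).

## Integration

Orbits are integrated with LSODA at rtol 1e-9 / atol 1e-11 by default, in
**log coordinates** for the positive components: a coordinate that starts
at zero stays exactly zero (plane invariance is structural), and a positive
coordinate can underflow to zero but never cross it. This choice was forced
by a failure mode of direct integration: once absolute solver error pushes
a near-zero population negative, the `z·h₁` structure amplifies the
excursion exponentially. In log space the issue cannot arise, and accuracy
on deep population crashes is relative rather than absolute. Output samples
below 1e-12 in magnitude are snapped to zero.

## Persistence

Uniform persistence is certified by the average Lyapunov function
`L = x^{m₁}y^{m₂}z^{m₃}`: positivity of
`κ = m₁f₁ + m₂g₁ + m₃h₁` at every boundary equilibrium, which reduces to
the three closed-form conditions (prey-only invadable by both consumers;
scavenger invades `P2`; predator invades `P3`) plus `m₁ > m₂δ + m₃μ` for
the origin. Default weights are `m₁ = 1`, `m₂ = m₃ = 1e-3` — the criterion
only needs *some* positive weights, and a dominant `m₁` keeps `κ(P0) > 0`
for any mortality values. All inequalities are strict; a zero margin fails.
The planar no-cycle conditions are checked pointwise on a 200×200
log-spaced grid (the xy-subsystem Dulac expression with weight `1/(xy)`;
the xz one, `−γ/z − ν₂/x`, is negative identically), reported as
holds/inconclusive with extremes — a grid verdict, not a symbolic proof.
The criterion is sufficient only: the reference set fails condition (i)
yet its attractors are interior; conversely a persistent-by-criterion
verdict is corroborated in the tests by simulated orbits staying above a
1e-4 floor, on a parameter set chosen so the floor is visible in double
precision (strongly persistent sets with huge relaxation oscillations can
have floors below representable numbers).

## Optimal harvesting

The control problem maximizes discounted net revenue
`∫₀^{Tf} e^{−δ₁T}[(p₁−ν₁q₁E₁X₂²)q₁E₁X₂² + (p₂−ν₂q₂E₂X₃²)q₂E₂X₃²
− C₁E₁ − C₂E₂] dT` over effort paths clamped to `[0, Eᵢmax]`. The economic
constants ν₁, ν₂ here are diminishing-returns coefficients, a different
object from the dimensionless harvesting rates that reuse the symbols —
the two live in different types (`EconParams` vs `NonDimParams`) so they
cannot be confused programmatically.

Everything is kept in the **present-value convention**: the Hamiltonian is
`H = L + λ·f` with the discount inside `L`, adjoints satisfy
`dλ/dT = −∂H/∂X` with `λ(Tf) = 0`, and the stationarity controls are

    E₁* = clip((e^{−δ₁T}(p₁q₁X₂² − C₁) − λ₂q₁X₂²)
               / (2e^{−δ₁T}ν₁q₁²X₂⁴), 0, E₁max)

(symmetrically for E₂*). A current-value formulation (adjoints scaled by
`e^{δ₁T}`) is algebraically equivalent; mixing the two conventions is a
known source of sign slips, so the implementation derives the adjoint
equations from `−∂H/∂X` directly and a test verifies them against a
finite-difference Hamiltonian gradient — an oracle that is convention-free.
When a harvested population is numerically extinct (< 1e-8) the control is
defined as 0: the formulas divide by `X²`–`X⁴`, and harvesting nothing at
cost `C·E > 0` can never be optimal.

The two-point boundary value problem is solved by the forward–backward
sweep: RK4 states forward on a fixed grid (default 2001 points), RK4
adjoints backward from the transversality condition, control update from
the stationarity formula with relaxation `E ← 0.5·E_old + 0.5·E_formula`
(plain updates can oscillate on this problem; 0.5 is the standard
stabilizer). Convergence requires the sup-norm control change below 1e-6
*and* relative revenue change below 1e-8; the per-iteration change history
is returned. Effort caps default to 1.0 (exposed in config). The scenario
suite runs none / E₁-only / E₂-only / both with excluded controls pinned to
zero; since enlarging the admissible set cannot decrease the optimum,
`J(both) ≥ J(single) ≥ J(none) = 0` is asserted up to solver tolerance.

## Problem sizes and defaults in the shipped analyses

Equilibrium searches use 64 Latin-hypercube starts (seeded); nullcline
scans 600 bracket points; orbit classification 3000 + 2000 time units at
step 0.05; the unharvested instability onset is reported on a 0.01-step
β-grid over [11.5, 12.1] after Brent-locating the Liu crossing; scenario
comparisons in the tests use 501-point control grids (the default 2001
changes the revenue by well under 0.1%, per the grid-refinement test).

## Known limitations

* Chaos is an operational label (maxima-cluster overflow or non-repeating
  visiting order), aligned with visual inspection of bifurcation diagrams;
  the Lyapunov-exponent corroboration is an estimate, not a proof.
* Normal-form magnitudes (first Lyapunov coefficient, fold/flip
  coefficients of limit cycles) are convention-dependent and only signs are
  exposed; limit-cycle continuation and codim-2 (generalized-Hopf) analysis
  are out of scope.
* The persistence and Dulac verdicts are certificates when positive but
  prove nothing when negative (both criteria are sufficient only).
* The forward-backward sweep finds Pontryagin-stationary controls; for this
  strictly concave-in-effort revenue that is the maximizer, but no global
  optimality certificate is computed for perturbed economics.
* Boundedness is guaranteed only under `β² < 4αν₁ν₂`; outside it the
  integrator simply reports unbounded trajectories if they occur.
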