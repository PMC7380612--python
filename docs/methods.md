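# Methods

## Physical model and assumptions

The solver treats the printing nozzle as an infinitely long cylinder of
radius *A* carrying stationary, laminar, axially uniform, pressure-driven
flow of an incompressible generalized Newtonian fluid. Under these
assumptions the Navier–Stokes equations reduce to a single ODE in the
radial coordinate,

    G = (1/r) d/dr [ r η(γ̇) du/dr ],     γ̇ = −du/dr ≥ 0,

with constant axial pressure gradient G = (p₀ − p_L)/L. The sign
convention is G < 0 for flow in +z; user-facing interfaces accept a
positive "driving pressure" magnitude and negate internally. Entrance and
exit effects, inertia, transients, wall slip, non-circular cross sections,
and viscoelastic or time-dependent (thixotropic) rheology are outside the
model. A cell-laden ink is handled through its measured bulk rheology.

Integrating the ODE once gives σ(r) = −G r/2 for the shear stress
regardless of η(γ̇): the stress profile in a cylindrical channel is exactly
linear for *any* generalized Newtonian fluid. This is both a physical
result and the solver's strongest invariant — it is asserted to machine
precision across all material laws in the tests.

## Piecewise power-law interpolation

The viscosity law is interpolated on a log-spaced shear-rate grid
Γ̇₀ … Γ̇_N by segments η_i = K_i γ̇^(n_i−1). Requiring the reconstruction
to be continuous at every interior node and exact at the nodes fixes each
segment from its two endpoint viscosities:

    n_i = 1 + ln(η(Γ̇_i)/η(Γ̇_{i−1})) / ln(Γ̇_i/Γ̇_{i−1}),
    K_i = η(Γ̇_i) / Γ̇_i^(n_i−1).

Anchoring both endpoints is the unique choice consistent with continuity
plus node exactness; it makes interpolation errors vanish at the nodes and
reproduces Newtonian and pure power-law inputs exactly everywhere.
Consistencies are stored as log K and all powers are evaluated in log
space, so small exponents at large shear rates cannot overflow.

A measured (tabulated) viscosity curve is treated as *already* piecewise
power-law between its points (log-log linear interpolation); outside the
measured range the end viscosities are held constant, i.e. the safest
physical extrapolation of Newtonian plateaus.

Defaults: grid 10⁻⁶ to 10⁸ s⁻¹; N = 1000 intervals for profile
computation, N = 150 inside the rheometry fit (where the forward model is
evaluated hundreds of times and 150 intervals already reproduce flow rates
to ~10⁻⁵ relative). The region below Γ̇₀ — a vanishingly thin core at the
channel axis — is absorbed into segment 1, whose exponent is ≈ 1 for any
plateaued law, making the extension exact in the limit. If the wall shear
rate exceeds Γ̇_N the solver raises an explicit grid-exhausted error rather
than extrapolating a fitted law silently; `auto_extend=True` re-interpolates
with a 10× larger maximum (up to four times).

The stress reconstruction K_i γ̇^{n_i} must be strictly increasing
(n_i > 0) for the stress balance to invert uniquely; laws that violate this
(e.g. a 3-parameter Carreau–Yasuda law with α ≥ 1 at high shear) are
rejected with a clear error instead of producing an unphysical profile.

## Exact solution

With the segments fixed, the stress balance σ(r) = −G r/2 inverts per
segment to γ̇_i(r) = (−G r / 2K_i)^{1/n_i}. The shell boundaries are the
radii R_i = 2 K_i Γ̇_i^{n_i}/(−G) where the shear rate crosses a grid node;
the wall lies in shell k with R_{k−1} ≤ A ≤ R_k (when A coincides with a
boundary, either shell gives the same values by continuity). Integrating
γ̇ inward from the no-slip wall and matching velocity at every shell
boundary yields, for r in shell i,

    u_i(r) = w_k γ̇_k(A) A − w_i γ̇_i(r) r − Σ_{b=i+1..k} R_b Γ̇_b (w_b − w_{b−1}),

with w_i = n_i/(n_i + 1). The flow rate uses the shear-rate route
Q = π ∫ r² γ̇ dr (integration by parts with no slip), summed in closed form
per shell; a second, independent closed form from the direct velocity
integral serves as an internal self-check at 10⁻¹⁰ relative. Averages of
velocity, shear rate, viscosity and stress are *area-weighted* over the
cross-section, (2/A²)∫ f(r) r dr, each analytic per shell. Area weighting
(rather than flux weighting) is a deliberate choice: it corresponds to the
question "what does a material element at a uniformly random position in
the cross-section experience", which is the relevant average for cell-damage
estimates; the stress average is then exactly ⅔ of the wall stress. The
viscosity average has a removable exponent at n_i = 1/3 (handled by a log
form) and genuinely diverges for an unbounded-zero-shear law (pure power
law with n < 1/3 at the axis), in which case infinity is reported.

The flow-rate-driven solve exploits strict monotonicity of Q(|G|): a
Newtonian initial guess based on the zero-shear viscosity, geometric
bracket expansion (treating gradients that exhaust the grid as "above
target"), then Brent refinement on log|G| to 10⁻⁸ relative in Q.

## Validation oracles

Two independent references, deliberately sharing no code with the solver:

1. **Closed form.** For η = η̃₀/(1 + Kγ̇) the stress relation inverts
   globally: γ̇(r) = s/(η̃₀ − Ks) with s = −G r/2, and the velocity has the
   elementary antiderivative
   u(r) = (c/b)[(η̃₀/b) ln((η̃₀ − br)/(η̃₀ − bA)) − (A − r)], c = −G/2,
   b = Kc. The antiderivative was re-derived here and is unit-tested
   against numeric quadrature and by differentiation before being used as
   truth. The stress of this law saturates at η̃₀/K; driving conditions
   whose wall stress reaches that bound have no bounded solution and raise
   a validity error.

2. **Brute force.** For any supported law, the scalar stress balance
   η(γ̇)γ̇ = −G r/2 is solved by bracketed root finding (Brent, relative
   tolerance 10⁻¹³, bracket expanded geometrically to at most 10¹² s⁻¹) at
   each radius, and the velocity follows by high-order quadrature (cubic
   spline antiderivative for profiles; adaptive quadrature of the stress
   integral Q = (π/c³)∫ γ̇(s) s² ds for flow rates, epsrel 10⁻¹⁰).

At N = 1000 the piecewise solution agrees with these references to ~10⁻⁴
relative for the simplified law (whose viscosity has a log-log kink the
log-spaced grid must resolve) and ~10⁻⁷ for a smooth five-parameter
Carreau–Yasuda hydrogel; errors fall monotonically as N doubles.

## Capillary rheometry fit

The inverse problem maps measured (p_j, Q_j) pairs from a needle of known
radius and length to 3-parameter Carreau–Yasuda values. Each pressure is
applied fully across the needle (the cartridge bore is wide, so its
pressure drop is neglected), G_j = −p_j/L. Levenberg–Marquardt least
squares (MINPACK via SciPy) runs in log-parameter space, which enforces
positivity without constraints and equalises scales across parameters that
span decades. The automatic start takes η̃₀ from the lowest-pressure point
via Hagen–Poiseuille, γ̇_c as the Newtonian wall shear rate there, and
α = 0.7. Trial parameter sets for which no solution exists (non-monotone
stress, or wall shear rates beyond any extended grid) return a large flat
penalty residual, so the optimizer rejects the step and retreats.

Two objectives are offered. The default minimises absolute flow-rate
residuals Σ(Q_meas − Q_model)². Because Q spans ~three decades across a
20–200 kPa sweep, absolute residuals are dominated by the highest-pressure
points; under multiplicative measurement noise this leaves η̃₀ and γ̇_c
(which live in the low-pressure data) weakly determined. The
`relative_residuals` option minimises Σ(Q_meas/Q_model − 1)² instead — the
maximum-likelihood weighting when errors have constant coefficient of
variation, as scale-based flow measurements do — and is what the noisy
recovery experiments use. Parameter uncertainty is reported as standard
errors of the log parameters (≈ relative standard errors) from the
Gauss–Newton covariance; a nearly Newtonian flow curve leaves γ̇_c and α
unidentified, which shows up as such standard errors ≫ 1 rather than as a
failure.

## Synthetic data

The generators emulate the standard bench experiment: a 21G blunt needle
(28 mm × 551 µm inner diameter), pressure stepped 20→200 kPa in 20 kPa
increments, and multiplicative flow-rate noise with fixed coefficient of
variation (1% by default in the recovery experiments — the repeatability
of a precision-scale flow measurement). Viscosity tables get log-normal
multiplicative noise at the grid nodes. All fixtures are pure functions of
(parameters, seed). What the synthetic data does *not* model: pressure
transients between steps, cartridge drainage, evaporation at the needle
tip, wall slip, and Bagley-type entrance corrections — so passing recovery
tests demonstrate identifiability and correctness of the inverse machinery,
not robustness to those systematic effects in real measurements.

## Numerical choices and problem sizes

- Interpolant continuity is validated at construction (relative jump at
  interior nodes ≤ 10⁻¹²; constructed interpolants sit near 10⁻¹⁵).
- Flow-driven solves converge Q to 10⁻⁸ relative; the internal two-route
  flow-rate self-check holds at 10⁻¹⁰.
- Acceptance and test experiments use N = 1000 for profile comparisons
  (matching typical practice), 801–1501 comparison radii, 20 random
  materials for the round-trip study and 50 noise replicates for the
  recovery study — sizes at which every reported quantity is stable to
  well below its tolerance.
- CSV writers print 17 significant digits and readers parse with
  round-trip float precision, so file round trips are lossless.

## Known limitations

- Yield-stress materials (unbounded zero-shear viscosity with a stress
  plateau) are not supported; the simplified-CY law errors out when the
  wall stress reaches its saturation bound rather than predicting a plug.
- The five-parameter Carreau–Yasuda model is not fittable from a single
  flow curve (under-determined); only the 3-parameter fit is provided.
- Averages are area-weighted; flux-weighted averages (what a cell *passing
  through* the nozzle samples, biased toward the fast core) would differ
  and are not implemented.
- The reported centreline viscosity is the segment-0 power law evaluated
  at the grid minimum — for plateaued laws this is the zero-shear
  viscosity to interpolation accuracy, but for a pure power law the true
  centreline viscosity is infinite.
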