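# Methods

## The model

`kkpolar` models steady, isothermal transport of a dilute aqueous
non-electrolyte across a horizontal, porous, symmetric, electrically neutral
selective membrane M. The compartment above the membrane holds the
concentrated solution (C_h, pressure P_h), the one below the dilute solution
(C_l, P_l). Because the solutions are not stirred, diffusion builds unstirred
concentration boundary layers (CBLs) of thicknesses δ_l and δ_h on the two
faces. The CBLs act as non-selective pseudo-membranes (reflection coefficient
0, solute permeability ω = D/(RTδ)) in series with M, so the concentrations
at the membrane faces, C_e (lower) and C_i (upper), differ from the bulk
values and only the *polarized* osmotic force Δπ_m = RT(C_i − C_e) acts on
the membrane.

The bare membrane is characterized by the Kedem–Katchalsky coefficients
L_p (hydraulic permeability, m³ N⁻¹ s⁻¹), σ_m (reflection coefficient) and
ω_m (solute permeability, mol N⁻¹ s⁻¹). For the composite sandwich, the K-K
flux laws are rescaled by four dimensionless polarization coefficients,

    J_vs = ζ_p L_p (ΔP − ζ_v σ_m Δπ)
    J_ss = ζ_s ω_m Δπ + C̄ (1 − ζ_a σ_m) J_vs

with ΔP = P_h − P_l, Δπ = RT(C_h − C_l). All four equal to 1 recovers the
classical equations. The working assumptions throughout are ζ_p = 1
(hydraulic permeability is insensitive to the layers) and ζ_a = ζ_s; a
solver flag allows an independent ζ_a for sensitivity studies.

The central quantity is the diffusive coefficient ζ_s = ω_s/ω_m — the
fraction of the bare membrane's solute permeability that survives
polarization. The package provides four algebraically related routes to it:

1. **Series-resistance form** (`zeta_s_series`): composing
   ω_s⁻¹ = ω_m⁻¹ + ω_l⁻¹ + ω_h⁻¹ gives
   ζ_s = D_l D_h / [D_l D_h + RT ω_m (D_h δ_l + D_l δ_h)], always in (0, 1].
2. **Rational form** (`rational_coefficients` / `zeta_from_jvm`):
   eliminating C_e and C_i from the steady-state layer balances expresses
   ζ_s = (J³ + φ0 J² + φ1 J + φ2)/(μ0 J − μ1) as a function of the membrane
   volume flux J = J_vm, with a pole at J* = μ1/μ0. Values outside [0, 1]
   are returned raw with a `physical` flag — clamping would hide where the
   branch leaves the physical region.
3. **Zero-flux limit** (`zeta_zero_flux`): the J_vm → 0 limit of the rational
   form. Its denominator omits the D_l D_h membrane term that the series
   form retains, so the two disagree (the limit expression can even exceed 1
   for thin layers). Both are implemented as stated; the package documents
   rather than reconciles the inconsistency. The series form is the one the
   brute-force system reproduces.
4. **Self-consistent cubic** (`cubic_coefficients` / `solve_zeta_cubic`):
   substituting the flux law J_vm = L_p(ΔP − σ_m ζ_s Δπ) into the rational
   form gives Z1 ζ³ + Z2 ζ² + Z3 ζ + Z4 = 0. The degree collapses when
   Δπ = 0 or σ_m = 0 (Z1 = Z2 = 0).

### Mean-concentration convention

The classical solute law uses the logarithmic mean
C̄ = (C_h − C_l)/ln(C_h/C_l); the steady-state layer balances use arithmetic
means C̄_l = ½(C_e + C_l), C̄_h = ½(C_h + C_i), C̄_s = ½(C_h + C_l). The two
conventions differ by <1% for concentration ratios near 1 but diverge badly
as C_l → 0. Because the rational and cubic forms are exact eliminations of
the layer-balance system, their μ0/Z coefficients use the arithmetic C̄_s by
default (`cbar_mode="arithmetic"`); with the log-mean the closed forms would
drift away from the brute-force solution at large ratios. The classical and
modified K-K flux functions default to the log-mean (falling back to the
arithmetic mean when a concentration is zero, where the log-mean is
undefined).

### Sign conventions

Positive solute flux runs from the h (upper, concentrated) side to the l
side; ΔP = P_h − P_l, Δπ = RT(C_h − C_l); negative J_vm means volume flows
l → h (pure osmosis at ΔP = 0 gives J_vm < 0).

## The brute-force reference solver

`steady_state_solve` treats the raw coupled system — lower-layer flux,
upper-layer flux, system flux, and the membrane volume-flux law — as three
equations in (C_e, C_i, J_vm), with ζ_s fixed at the series value. Two
independent routes are implemented:

* a damped fixed-point iteration alternating the volume-flux law with the
  explicit boundary-concentration solution (damping 0.5 by default; the map
  is strongly contractive at the presets' scales because J δ/(2D) ≪ 1), and
* a multidimensional root solve (`scipy.optimize.root`, hybr) on the raw
  residuals, with seeded randomized restarts, scaled so all three unknowns
  are O(1).

The convergence metric is the maximum of the three equation defects, each
normalized by its natural flux scale (ω_m|Δπ| for solute, L_p(|ΔP| +
σ_m|Δπ|) for volume); default tolerance 1e-12. The default method runs the
fixed point and falls back to the root solve if it stalls; the test suite
checks the two routes agree to 1e-8 on seeded random instances. Every closed
form in the package is validated against this solver rather than against
another rearrangement of itself.

A subtlety worth knowing: the cubic's roots are fixed points of the
composition of the rational form with the flux law, and the flux law
approximates the polarized force by ζ_sΔπ — exact only at J_vm = 0. The cubic root therefore differs from the raw-system
ζ_s by O(J_vm) (≈1e-4 relative at the glucose preset's osmotic fluxes). The
cubic is certified in the tests by an independent bracketing root-find of
the closure relation itself, and by high-precision polynomial root oracles.

## Rayleigh coupling

For a horizontal membrane, solute accumulation makes a layer's
stratification top-heavy or bottom-heavy; the concentration Rayleigh number

    R_C = g ω_m ζ_s RT (∂ρ/∂C) δ⁴ (C_h − C_l) / (D² ρ ν)

diagnoses the onset of free convection (it is an algebraic diagnostic: no
fluid dynamics is simulated). Its inversion at a given layer concentration
drop Δc,  δ = [R_C D ρ ν / (g (∂ρ/∂C) Δc)]^(1/3),  and the quartic thickness
balance  c1 δ⁴ + c2 δ + c3 = 0  obtained by eliminating the boundary
concentrations are implemented per-side; at J_vm = 0 the quartic is
biquadratic with root (−c3/c1)^(1/4). The quartic's root choice — the
smallest strictly positive real root — keeps continuity with the δ → 0,
R_C → 0 limit; all real roots and a scaled residual are reported.

The implicit surface ζ_s = f(R_Cl, J_vm) for the purely osmotic regime
(ΔP = 0, C_l = 0, layer thickness tied to ζ_s through the symmetric series
form) is evaluated verbatim, although its bracketed sums mix dimensions
(pure numbers are added to flux-scaled terms). A dimensionally consistent
`"reconstructed"` residual, rebuilt from the lower-layer quartic with the
same substitutions, is available via `mode="reconstructed"`; it is this
package's own derivation and is clearly non-canonical. Root finding brackets the residual on a grid logarithmic in
(1/ζ − 1) — the quartic branch is extremely steep as ζ → 0 — and refines by
bisection to machine precision. At J_vm = 0 the residual reduces to
R_Cl ν ρ [1 + 1/(4RTω_m)], so the surface touches the physical branch only
at the origin, where ζ_s = 1 anchors it.

Two sign facts follow from the ethanol preset's negative ∂ρ/∂C (ethanol
lowers the density of water): its Rayleigh numbers are negative in the
standard orientation (stable stratification), and the literal implicit
surface relation has no root in (0, 1] there. The convective-surface sweeps therefore
use the destabilizing orientation |∂ρ/∂C| (flag `abs_drho`), i.e. the
configuration in which the buoyancy actually drives convection; everywhere
else the signed slope is kept. On that branch ζ_s increases as R_Cl
decreases and as J_vm decreases (becomes more negative): weaker convection
and stronger osmotic inflow both deepen polarization.

## Parameters and defaults

| symbol | meaning | glucose | ethanol | unit |
|---|---|---|---|---|
| L_p | hydraulic permeability | 5e-12 | 5e-12 | m³ N⁻¹ s⁻¹ |
| σ_m | reflection coefficient | 0.068 | 0.025 | – |
| ω_m | solute permeability | 8e-10 | 14.3e-10 | mol N⁻¹ s⁻¹ |
| D | diffusion coefficient | 0.69e-9 | 1.57e-9 | m² s⁻¹ |
| ρ_l | solvent density | 998 | 998 | kg m⁻³ |
| ν_l | kinematic viscosity | 1.012e-6 | 1.012e-6 | m² s⁻¹ |
| ∂ρ/∂C | density slope | +0.0600 | −0.0090 | kg mol⁻¹ |

Density/viscosity of mixed upper solutions follow the dilute expansions with
α₁ = 6.01e-5, γ₁ = 3.95e-4 (glucose), α₂ = −9.02e-6, γ₂ = 1.82e-5 (ethanol),
all m³ mol⁻¹. Both presets are for the Nephrophan cellulose dialysis
membrane; every preset field carries a provenance note. Temperature is never
part of the published characterization, so T = 295 K is an explicit,
overridable package default (R = 8.314 J mol⁻¹ K⁻¹), and the CBL thicknesses
are package defaults (δ = 5e-4 m, documented range 1e-4–1e-3 m), both
flagged `[DEFAULT-not-from-paper]`. The 200 cm³ compartment volume is
metadata only — there is no mass-balance dynamics in scope.

## Synthetic instances

`random_instance(seed)` draws reproducible parameter bundles for property
tests: a preset is chosen, its membrane/diffusion coefficients scaled by
log-uniform factors in [0.5, 2], thicknesses uniform in the documented CBL
range, C_l uniform in [0.5, 50] mol m⁻³, Δπ uniform in ±100 kPa (C_h
back-computed, clipped at zero), ΔP uniform in ±2 kPa — the force ranges the
zero-flux surfaces are plotted over. These bundles emulate the *parameter
space* of the physical system, not real measured data: they contain no
measurement noise, no transient layer growth, and no convection-cell
structure, so the passing identity tests demonstrate internal mathematical
consistency of the model at realistic scales, not agreement with
experiments.

## Numerical choices

* Polynomial roots: numpy companion-matrix roots with three Newton polish
  steps; leading coefficients below 1e-14 of the largest |coefficient| are
  trimmed first (degree collapse is detected, not fudged). Real roots are
  those with |Im| ≤ 1e-8(1 + |Re|).
* Physical cubic root: the real root in [0, 1] (±1e-9 slack for rounding)
  minimizing the closure defect |zeta_from_jvm(jvm_self_consistent(ζ)) − ζ|;
  ties break toward the
  series value.
* Pole guard: the rational form raises a `PoleError` (carrying J* = μ1/μ0)
  when |μ0 J − μ1| ≤ 1e-12 |μ1|; the sweep engine flags such grid points and
  continues.
* Degenerate inputs: vanishing layers collapse face concentrations onto the
  bulk; zero thickness is an infinite-permeability sentinel in ω_l and a
  domain error where the formulas divide by δ_l δ_h; all-zero cubic
  coefficients raise rather than returning arbitrary roots.
* Problem sizes: identity checks run over 1000 (limit identity), 500
  (series), 200 (oracle equivalence/closure) seeded instances and complete
  in about a second — the identities are algebraic, so coverage matters more
  than scale.

## Known limitations

* Steady state only; no transient CBL growth, no electrolytes, no fitting of
  L_p, σ_m, ω_m from experimental series.
* The zero-flux expression and the series form genuinely disagree (see route
  3 above); users comparing the two at thin layers will see values above 1
  from the former — by design they are reported raw.
* The implicit convective surface inherits the dimensional inconsistency of
  its source relation; the reconstructed mode is offered for comparison but
  neither is validated against fluid-dynamics simulation.
* Published quantitative results for this system exist only as figures, so
  the test suite validates the implemented relations against each other, a
  brute-force solver, and symbolic/polynomial oracles, plus the figures'
  qualitative shapes (monotonicity, force-ratio sheets, surface directions).
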