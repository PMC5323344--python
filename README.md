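# kkpolar

Concentration polarization in Kedem–Katchalsky membrane transport of
non-electrolyte solutions.

When a selective membrane separates two unstirred aqueous solutions, the
solute it rejects piles up in thin diffusive films — concentration boundary
layers (CBLs) — on its faces. The layers act as pseudo-membranes in series
with the real one and eat part of the osmotic driving force, so the fluxes a
transport model predicts from the *bulk* concentrations overestimate what
the membrane actually delivers. `kkpolar` quantifies that loss through the
diffusive concentration polarization coefficient

    zeta_s = omega_s / omega_m  in (0, 1],

the ratio of the composite system's solute permeability to the bare
membrane's (1 = no polarization). The package is aimed at membrane
biophysicists and engineers who need ζ_s as a function of the volume flux
J_vm, the osmotic force Δπ = RT(C_h − C_l), the hydrostatic force
ΔP = P_h − P_l, the layer thicknesses δ_l, δ_h, and — for horizontal
membranes where solutal buoyancy stirs the layers — the concentration
Rayleigh number R_C.

It implements, and cross-validates against a brute-force solver of the raw
coupled flux equations:

* the classical and polarization-modified Kedem–Katchalsky flux laws
  (J_v = L_p(ΔP − σ_mΔπ), J_s = ω_mΔπ + C̄(1 − σ_m)J_v and their ζ-scaled
  forms);
* the series-resistance form ζ_s = D_lD_h/[D_lD_h + RTω_m(D_hδ_l + D_lδ_h)];
* boundary-face concentrations C_e, C_i at a given flux, and the rational
  form ζ_s(J_vm) = (J³ + φ₀J² + φ₁J + φ₂)/(μ₀J − μ₁) with its zero-flux
  limit and pole diagnostics;
* the self-consistent cubic Z₁ζ³ + Z₂ζ² + Z₃ζ + Z₄ = 0 obtained by
  eliminating J_vm, with physical-root selection;
* concentration Rayleigh numbers, the inverse thickness relation
  δ = [R_C Dρν/(g(∂ρ/∂C)Δc)]^(1/3), the quartic thickness balance, and the
  implicit convective surface ζ_s = f(R_Cl, J_vm).

Packaged presets describe the Nephrophan dialysis membrane in aqueous
glucose and ethanol; see `docs/methods.md` for the full model, conventions
and limitations.

## Worked example

```python
import kkpolar as kk

preset = kk.get_preset("nephrophan-glucose")
conditions = kk.Conditions(C_l=1.0, C_h=50.0, dP=0.0, T=295.0)  # pure osmosis
geometry = preset.geometry()                                     # 0.5 mm CBLs

state = kk.steady_state_solve(preset.membrane, preset.solutions,
                              geometry, conditions)
print(f"dpi   = {conditions.dpi:.1f} Pa")
print(f"dpi_m = {state.dpi_m:.1f} Pa")
print(f"zeta_s = {state.zeta_s:.4f}, J_vm = {state.J_vm:.4e} m/s")
```

prints

```
dpi   = 120178.9 Pa
dpi_m = 31252.2 Pa
zeta_s = 0.2602, J_vm = -1.0626e-08 m/s
```

A 120 kPa bulk osmotic force shrinks to 31 kPa at the membrane faces: the
boundary layers absorb ~74% of it (ζ_s ≈ 0.26), and the surviving force
draws a volume flux of ~11 nm/s toward the concentrated side. The closed
forms reproduce this: `zeta_from_jvm(state.J_vm, ...)` returns the same ζ_s
to ten digits, and `zeta_cubic(...)` finds it without knowing the flux.

The `examples/` scripts walk through each capability (steady state, the
four ζ_s routes, force-surface sweeps, Rayleigh coupling), and the `kkpolar`
console command exposes the same operations from the shell:

```sh
kkpolar solve --preset nephrophan-glucose --Cl 1 --Ch 50 --dP 0
kkpolar zeta --mode zero-flux --Cl 1 --Ch 50 --dP 2hPa
kkpolar sweep --like convective-surface-ethanol --out surface.csv
```

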