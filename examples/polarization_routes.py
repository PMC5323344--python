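"""Compare every closed-form route to the polarization coefficient.

For one glucose configuration the script evaluates: the series-resistance
form, the rational form zeta_s(J_vm) at the brute-force steady-state flux,
its zero-flux limit, and the physical root of the self-consistent cubic.
The first two agree to ~1e-10 (they are rearrangements of the same system);
the zero-flux expression differs because it drops the membrane term from the
denominator, and the cubic root differs from the series value by O(J_vm).
"""

import kkpolar as kk

preset = kk.get_preset("nephrophan-glucose")
m, s = preset.membrane, preset.solutions
geometry = preset.geometry()
c = kk.Conditions(C_l=1.0, C_h=50.0, dP=300.0, T=295.0)

z_series = kk.zeta_s_series(m, s, geometry, c.T)
state = kk.steady_state_solve(m, s, geometry, c)
coeffs = kk.rational_coefficients(m, s, geometry, c)
z_rational = kk.zeta_from_jvm(state.J_vm, coeffs)
z_zero = kk.zeta_zero_flux(m, s, geometry, c)
cubic = kk.zeta_cubic(m, s, geometry, c)

print(f"series-resistance form          zeta_s = {z_series:.6f}")
print(f"rational form at solved J_vm    zeta_s = {z_rational.value:.6f} "
      f"(physical: {z_rational.physical})")
print(f"zero-flux limit expression      zeta_s = {z_zero:.6f}")
print(f"self-consistent cubic root      zeta_s = {cubic.physical_root:.6f} "
      f"(all real roots: {[f'{r:.3f}' for r in cubic.real_roots]})")
print(f"pole of the rational form at J_vm* = {coeffs.pole_jvm:.3e} m/s")
print()
print("The series and rational routes coincide; the zero-flux expression is")
print("only the J_vm -> 0 limit of the rational form, and the cubic root is")
print("the fixed point of substituting the flux law back into that form.")
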