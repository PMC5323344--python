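"""Solve the steady state of a glucose gradient across a Nephrophan membrane.

A 50 mol/m^3 glucose solution sits above the membrane, a 1 mol/m^3 solution
below, with no applied pressure. Unstirred 0.5 mm boundary layers polarize
the gradient: the script solves the raw coupled flux equations and prints how
much of the bulk osmotic force actually survives at the membrane faces.
"""

import kkpolar as kk

preset = kk.get_preset("nephrophan-glucose")
conditions = kk.Conditions(C_l=1.0, C_h=50.0, dP=0.0, T=295.0)
geometry = preset.geometry()  # symmetric 5e-4 m layers

state = kk.steady_state_solve(preset.membrane, preset.solutions, geometry, conditions)

print(f"bulk osmotic force  dpi   = {conditions.dpi:10.1f} Pa")
print(f"polarized force     dpi_m = {state.dpi_m:10.1f} Pa")
print(f"face concentrations C_e, C_i = {state.C_e:.3f}, {state.C_i:.3f} mol/m^3")
print(f"volume flux J_vm = {state.J_vm:.4e} m/s (negative: toward the concentrated side)")
print(f"solute flux J_ss = {state.J_ss:.4e} mol m^-2 s^-1")
print(f"zeta_s = {state.zeta_s:.4f}  (fraction of membrane permeability left"
      " after polarization)")
print(f"solver residual = {state.residual:.2e}")
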