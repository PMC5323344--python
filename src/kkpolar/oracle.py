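"""Brute-force steady-state solver for the layer/membrane/layer sandwich.

The raw coupled system couples three unknowns (C_e, C_i, J_vm) through

* the lower-layer solute flux   J_sl = D_l/delta_l*(C_e - C_l) + J_vm*Cbar_l,
* the upper-layer solute flux   J_sh = D_h/delta_h*(C_h - C_i) + J_vm*Cbar_h,
* the system solute flux        J_ss = zeta_s*omega_m*dpi
                                        + J_vm*(1 - zeta_a*sigma_m)*Cbar_s,
* the membrane volume flux      J_vm = Lp*[dP - sigma_m*R*T*(C_i - C_e)],

with Cbar_l = 0.5*(C_e + C_l), Cbar_h = 0.5*(C_h + C_i),
Cbar_s = 0.5*(C_h + C_l), and zeta_s fixed by the series-resistance form
(zeta_a = zeta_s, the working assumption). The steady state requires
J_sl = J_sh = J_ss simultaneously with the volume-flux law.

Every closed form in :mod:`kkpolar.core` is an algebraic rearrangement of
this system; this module solves it numerically with no such rearrangement
and serves as the independent reference in the test suite.

Two routes are provided: a damped fixed-point iteration alternating the
volume-flux law with the explicit boundary-concentration solution, and a
multidimensional root solve on the raw residuals (scipy ``root``). The
default ``"auto"`` method runs the fixed point and falls back to the root
solve (with seeded randomized restarts) if it stalls.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import root as _scipy_root

from .core import boundary_concentrations, jvm_membrane, zeta_s_series
from .errors import ConvergenceError, DomainError
from .params import (
    Conditions,
    LayerGeometry,
    MembraneParams,
    SolutionParams,
    SolverSettings,
    SteadyState,
)

__all__ = ["steady_state_solve", "zeta_effective", "raw_residuals"]


def _layer_fluxes(
    solutions: SolutionParams,
    geometry: LayerGeometry,
    conditions: Conditions,
    C_e: float,
    C_i: float,
    J_vm: float,
) -> tuple[float, float]:
    """(J_sl, J_sh): solute fluxes through the lower and upper layers."""
    Cl, Ch = conditions.C_l, conditions.C_h
    J_sl = solutions.D_l / geometry.delta_l * (C_e - Cl) + J_vm * 0.5 * (C_e + Cl)
    J_sh = solutions.D_h / geometry.delta_h * (Ch - C_i) + J_vm * 0.5 * (Ch + C_i)
    return J_sl, J_sh


def _system_flux(
    membrane: MembraneParams,
    conditions: Conditions,
    zeta_s: float,
    zeta_a: float,
    J_vm: float,
) -> float:
    """System solute flux J_ss from the polarized K-K law."""
    cbar_s = 0.5 * (conditions.C_h + conditions.C_l)
    return (
        zeta_s * membrane.omega_m * conditions.dpi
        + J_vm * (1.0 - zeta_a * membrane.sigma_m) * cbar_s
    )


def raw_residuals(
    membrane: MembraneParams,
    solutions: SolutionParams,
    geometry: LayerGeometry,
    conditions: Conditions,
    zeta_s: float,
    zeta_a: float,
    C_e: float,
    C_i: float,
    J_vm: float,
) -> tuple[float, float, float]:
    """Raw defects (J_sl - J_ss, J_sh - J_ss, J_vm - Lp[dP - sigma_m*RT*(C_i-C_e)])."""
    J_sl, J_sh = _layer_fluxes(solutions, geometry, conditions, C_e, C_i, J_vm)
    J_ss = _system_flux(membrane, conditions, zeta_s, zeta_a, J_vm)
    r3 = J_vm - jvm_membrane(membrane, conditions.dP, C_i, C_e, conditions.T)
    return (J_sl - J_ss, J_sh - J_ss, r3)


def _scales(
    membrane: MembraneParams,
    solutions: SolutionParams,
    geometry: LayerGeometry,
    conditions: Conditions,
) -> tuple[float, float]:
    """(solute-flux scale, volume-flux scale) used to normalize residuals."""
    Cl, Ch = conditions.C_l, conditions.C_h
    s_solute = max(
        membrane.omega_m * abs(conditions.dpi),
        solutions.D_l / geometry.delta_l * max(Ch, Cl, 1.0) * 1e-6,
        1e-30,
    )
    s_volume = max(
        membrane.Lp * (abs(conditions.dP) + membrane.sigma_m * abs(conditions.dpi)),
        1e-30,
    )
    return s_solute, s_volume


def _normalized_residual(
    membrane, solutions, geometry, conditions, zeta_s, zeta_a, C_e, C_i, J_vm
) -> float:
    r1, r2, r3 = raw_residuals(
        membrane, solutions, geometry, conditions, zeta_s, zeta_a, C_e, C_i, J_vm
    )
    s_s, s_v = _scales(membrane, solutions, geometry, conditions)
    return max(abs(r1) / s_s, abs(r2) / s_s, abs(r3) / s_v)


def steady_state_solve(
    membrane: MembraneParams,
    solutions: SolutionParams,
    geometry: LayerGeometry,
    conditions: Conditions,
    settings: SolverSettings | None = None,
    method: str = "auto",
    zeta_a: float | None = None,
    trace: list | None = None,
) -> SteadyState:
    """Solve the raw coupled system for (C_e, C_i, J_vm).

    Parameters
    ----------
    method : {"auto", "fixed_point", "root"}
        ``"fixed_point"`` iterates the volume-flux law against the explicit
        boundary-concentration solution with damping; ``"root"`` solves the
        raw residuals with a multidimensional root finder (seeded randomized
        restarts); ``"auto"`` tries the fixed point first and falls back.
    zeta_a : float, optional
        Independent advective coefficient for sensitivity studies; defaults
        to the series zeta_s (the model's working assumption).
    trace : list, optional
        If given, one dict per fixed-point iteration (iter, C_e, C_i, J_vm,
        residual) is appended to it.

    Returns
    -------
    SteadyState
        Converged state with the max normalized equation defect in
        ``residual``.

    Raises
    ------
    ConvergenceError
        If neither route reaches the tolerance; carries the best residual.
    """
    if settings is None:
        settings = SolverSettings()
    if geometry.delta_l <= 0 or geometry.delta_h <= 0:
        raise DomainError("steady-state solve requires delta_l, delta_h > 0")
    if method not in ("auto", "fixed_point", "root"):
        raise DomainError(f"unknown method {method!r}")

    zs = zeta_s_series(membrane, solutions, geometry, conditions.T)
    za = zs if zeta_a is None else zeta_a

    def res(Ce: float, Ci: float, J: float) -> float:
        return _normalized_residual(
            membrane, solutions, geometry, conditions, zs, za, Ce, Ci, J
        )

    best: tuple[float, float, float, float] | None = None  # (residual, Ce, Ci, J)

    # --- damped fixed point ------------------------------------------------
    if method in ("auto", "fixed_point"):
        C_e, C_i = conditions.C_l, conditions.C_h
        J = jvm_membrane(membrane, conditions.dP, C_i, C_e, conditions.T)
        d = settings.damping
        for it in range(settings.max_iter):
            C_i, C_e = boundary_concentrations(
                membrane, solutions, geometry, conditions, J, zs, za
            )
            J_new = jvm_membrane(membrane, conditions.dP, C_i, C_e, conditions.T)
            J = (1.0 - d) * J + d * J_new
            r = res(C_e, C_i, J)
            if trace is not None:
                trace.append(
                    {"iter": it, "C_e": C_e, "C_i": C_i, "J_vm": J, "residual": r}
                )
            if best is None or r < best[0]:
                best = (r, C_e, C_i, J)
            if r < settings.tol:
                break

    # --- raw-system root solve ---------------------------------------------
    if method == "root" or (
        method == "auto" and (best is None or best[0] >= settings.tol)
    ):
        s_s, s_v = _scales(membrane, solutions, geometry, conditions)
        c_scale = max(conditions.C_h, conditions.C_l, 1.0)

        def fun(x: np.ndarray) -> np.ndarray:
            Ce, Ci, J = x[0] * c_scale, x[1] * c_scale, x[2] * s_v
            r1, r2, r3 = raw_residuals(
                membrane, solutions, geometry, conditions, zs, za, Ce, Ci, J
            )
            return np.array([r1 / s_s, r2 / s_s, r3 / s_v])

        rng = np.random.default_rng(settings.seed)
        starts = [
            np.array(
                [
                    conditions.C_l / c_scale,
                    conditions.C_h / c_scale,
                    jvm_membrane(
                        membrane, conditions.dP, conditions.C_h, conditions.C_l,
                        conditions.T,
                    )
                    / s_v,
                ]
            )
        ]
        if best is not None:
            starts.insert(0, np.array([best[1] / c_scale, best[2] / c_scale, best[3] / s_v]))
        for _ in range(settings.n_restarts):
            starts.append(starts[-1] * (1.0 + 0.2 * rng.standard_normal(3)))
        for x0 in starts:
            sol = _scipy_root(fun, x0, method="hybr", options={"xtol": 1e-15})
            Ce, Ci, J = sol.x[0] * c_scale, sol.x[1] * c_scale, sol.x[2] * s_v
            r = res(Ce, Ci, J)
            if best is None or r < best[0]:
                best = (r, Ce, Ci, J)
            if r < settings.tol:
                break

    assert best is not None
    r, C_e, C_i, J = best
    if r > settings.tol:
        raise ConvergenceError(r)
    J_ss = _system_flux(membrane, conditions, zs, za, J)
    return SteadyState(
        C_e=C_e,
        C_i=C_i,
        J_vm=J,
        J_ss=J_ss,
        zeta_s=zs,
        dpi_m=conditions.RT * (C_i - C_e),
        residual=r,
        C_l=conditions.C_l,
        C_h=conditions.C_h,
    )


def zeta_effective(
    state: SteadyState, membrane: MembraneParams, conditions: Conditions
) -> float:
    """Back out zeta_s from a solved state via the system flux law.

    With zeta_a = zeta_s the system flux law is linear in zeta_s:

    J_ss = zeta_s*omega_m*dpi + J_vm*(1 - zeta_s*sigma_m)*Cbar_s
    =>  zeta_s = (J_ss - J_vm*Cbar_s) / (omega_m*dpi - J_vm*sigma_m*Cbar_s)

    Raises
    ------
    DomainError
        If the linear coefficient omega_m*dpi - J_vm*sigma_m*Cbar_s is
        degenerate (zeta_s undefined).
    """
    cbar_s = 0.5 * (conditions.C_h + conditions.C_l)
    denom = membrane.omega_m * conditions.dpi - state.J_vm * membrane.sigma_m * cbar_s
    scale = membrane.omega_m * abs(conditions.dpi) + abs(state.J_vm) * cbar_s
    if scale == 0.0 or abs(denom) <= 1e-14 * scale:
        raise DomainError("zeta_effective is undefined: degenerate linear coefficient")
    return (state.J_ss - state.J_vm * cbar_s) / denom
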