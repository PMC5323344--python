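"""Concentration Rayleigh numbers and the convective coupling of layer thickness.

For a horizontal membrane, solute accumulating in a boundary layer changes
the local density; when the stratification is top-heavy, free convection sets
in and limits the layer thickness. The concentration Rayleigh number of a
layer of thickness delta,

    R_C = g * omega_m * zeta_s * R*T * (drho/dC) * delta^4 * (C_h - C_l)
          / (D^2 * rho * nu),

compares solutal buoyancy against diffusive/viscous dissipation. This module
implements that diagnostic, its inversion for delta at a given concentration
drop, the quartic thickness balance obtained by eliminating the boundary
concentrations, and the implicit surface zeta_s = f(R_Cl, J_vm) for the
purely osmotic regime (dP = 0, C_l = 0). No fluid dynamics is simulated;
these are algebraic diagnostics of the onset balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError
from .params import (
    Conditions,
    LayerGeometry,
    MembraneParams,
    QuarticCoefficients,
    R_GAS,
    SolutionParams,
)

__all__ = [
    "G_STANDARD",
    "rayleigh_number",
    "delta_from_rayleigh",
    "quartic_coefficients",
    "QuarticSolution",
    "solve_delta_quartic",
    "delta_from_zeta_symmetric",
    "convective_surface_residual",
    "ZetaSurfaceResult",
    "implicit_zeta_surface",
]

#: Standard gravitational acceleration, m s^-2.
G_STANDARD = 9.81


def _check_side(side: str) -> None:
    if side not in ("l", "h"):
        raise DomainError(f"side must be 'l' or 'h', got {side!r}")


def rayleigh_number(
    side: str,
    membrane: MembraneParams,
    solutions: SolutionParams,
    geometry: LayerGeometry,
    conditions: Conditions,
    zeta_s: float,
    g: float = G_STANDARD,
) -> float:
    """Concentration Rayleigh number of one boundary layer.

    R_Cl = g*omega_m*zeta_s*R*T*(drho/dC)*delta_l^4*(C_h - C_l)/(D_l^2*rho_l*nu_l)
    and analogously for side "h". Scales with the fourth power of the layer
    thickness; zero thickness gives zero. A negative value (e.g. a solute
    that lowers the density) indicates a convectively stable stratification
    and is returned as-is.
    """
    _check_side(side)
    D, rho, nu = solutions.D(side), solutions.rho(side), solutions.nu(side)
    if D <= 0 or rho <= 0 or nu <= 0:
        raise DomainError("D, rho and nu must be > 0")
    delta = geometry.delta(side)
    return (
        g
        * membrane.omega_m
        * zeta_s
        * conditions.RT
        * solutions.drho_dC
        * delta**4
        * (conditions.C_h - conditions.C_l)
        / (D**2 * rho * nu)
    )


def delta_from_rayleigh(
    side: str,
    solutions: SolutionParams,
    rayleigh: float,
    concentration_drop: float,
    g: float = G_STANDARD,
) -> float:
    """Layer thickness consistent with a given Rayleigh number.

    delta = {R_C * D * rho * nu / [g*(drho/dC)*dc]}^(1/3)

    where dc is the concentration drop across the layer (C_e - C_l for the
    lower side, C_h - C_i for the upper). R_C = 0 gives delta = 0; scaling
    R_C by 8 doubles delta.

    Raises
    ------
    DomainError
        If the drop is not positive, the buoyancy product (drho/dC)*dc is not
        positive (convectively stable configuration), or R_C < 0.
    """
    _check_side(side)
    if concentration_drop <= 0:
        raise DomainError("concentration drop must be > 0")
    if solutions.drho_dC * concentration_drop <= 0:
        raise DomainError(
            "buoyancy product (drho/dC)*dc <= 0: convectively stable configuration"
        )
    if rayleigh < 0:
        raise DomainError("Rayleigh number must be >= 0 here")
    if rayleigh == 0.0:
        return 0.0
    D, rho, nu = solutions.D(side), solutions.rho(side), solutions.nu(side)
    return (
        rayleigh * D * rho * nu / (g * solutions.drho_dC * concentration_drop)
    ) ** (1.0 / 3.0)


def quartic_coefficients(
    side: str,
    membrane: MembraneParams,
    solutions: SolutionParams,
    conditions: Conditions,
    zeta_s: float,
    J_vm: float,
    rayleigh: float,
    g: float = G_STANDARD,
) -> QuarticCoefficients:
    """Coefficients of the thickness balance c1*delta^4 + c2*delta + c3 = 0.

    Lower layer (side "l"):
        c1 = g*(drho/dC)*{zeta_s*omega_m*dpi
             + J_vm*[0.5*(C_h - C_l) - zeta_s*sigma_m*(C_h + C_l)]}
        c2 = -0.5*J_vm*R_Cl*D_l*nu_l*rho_l
        c3 = -R_Cl*D_l^2*nu_l*rho_l

    Upper layer (side "h"):
        c1 = g*(drho/dC)*{zeta_s*omega_m*dpi
             - J_vm*[0.5*(C_h - C_l) + zeta_s*sigma_m*(C_h + C_l)]}
        c2 = +0.5*J_vm*R_Ch*D_h*nu_h*rho_h
        c3 = -R_Ch*D_h^2*nu_h*rho_h

    Note the sign flip of the J_vm terms between the two sides (advection
    thins the donor layer and thickens the receiver layer). At J_vm = 0 the
    linear term vanishes and the balance is biquadratic with the closed-form
    positive root (-c3/c1)^(1/4).
    """
    _check_side(side)
    D, rho, nu = solutions.D(side), solutions.rho(side), solutions.nu(side)
    Cl, Ch = conditions.C_l, conditions.C_h
    sgn = 1.0 if side == "l" else -1.0
    c1 = g * solutions.drho_dC * (
        zeta_s * membrane.omega_m * conditions.dpi
        + sgn * J_vm * (0.5 * (Ch - Cl) - sgn * zeta_s * membrane.sigma_m * (Ch + Cl))
    )
    c2 = -sgn * 0.5 * J_vm * rayleigh * D * nu * rho
    c3 = -rayleigh * D**2 * nu * rho
    return QuarticCoefficients(side=side, c1=c1, c2=c2, c3=c3)


@dataclass(frozen=True)
class QuarticSolution:
    """Result of the quartic thickness solve.

    ``delta`` is the smallest strictly positive real root (None when no such
    root exists — "no physical thickness"); ``real_roots`` lists all real
    roots; ``residual`` is |c1*d^4 + c2*d + c3| scaled by the largest term
    magnitude at the root.
    """

    delta: float | None
    real_roots: tuple[float, ...]
    residual: float
    physical: bool


def solve_delta_quartic(coeffs: QuarticCoefficients) -> QuarticSolution:
    """Solve c1*delta^4 + c2*delta + c3 = 0 for the physical thickness.

    The smallest strictly positive real root is selected: it connects
    continuously to the delta -> 0 limit as R_C -> 0. Companion-matrix roots
    are polished with Newton steps and certified by a scaled residual.

    Raises
    ------
    DomainError
        If the leading coefficient is zero.
    """
    c1, c2, c3 = coeffs.as_tuple()
    if c1 == 0.0:
        raise DomainError("leading quartic coefficient is zero")
    if c2 == 0.0:
        # biquadratic degenerate: delta^4 = -c3/c1
        ratio = -c3 / c1
        if ratio < 0:
            return QuarticSolution(None, (), 0.0, False)
        d = ratio**0.25
        roots = (-d, d) if d > 0 else (0.0,)
        resid = abs(coeffs(d)) / max(abs(c1) * d**4, abs(c3), 1e-300)
        return QuarticSolution(d if d > 0 else None, roots, resid, d > 0)

    roots = np.roots([c1, 0.0, 0.0, c2, c3])

    def f(x: complex) -> complex:
        return c1 * x**4 + c2 * x + c3

    def fp(x: complex) -> complex:
        return 4.0 * c1 * x**3 + c2

    polished = []
    for r in roots:
        z = complex(r)
        for _ in range(3):
            d = fp(z)
            if d == 0:
                break
            z = z - f(z) / d
        polished.append(z)
    arr = np.asarray(polished)
    real = np.sort(arr.real[np.abs(arr.imag) <= 1e-8 * (1.0 + np.abs(arr.real))])
    positive = [float(r) for r in real if r > 0]
    if not positive:
        return QuarticSolution(None, tuple(float(r) for r in real), math.inf, False)
    d = min(positive)
    scale = max(abs(c1) * d**4, abs(c2) * d, abs(c3))
    resid = abs(coeffs(d)) / scale
    return QuarticSolution(d, tuple(float(r) for r in real), resid, True)


def delta_from_zeta_symmetric(
    zeta_s: float, D: float, omega_m: float, T: float
) -> float:
    """Thickness of equal CBLs implied by a symmetric polarization value.

    Inverts the symmetric series form (delta_l = delta_h = delta,
    D_l = D_h = D):  delta = D/(2*R*T*omega_m) * (1/zeta_s - 1).
    zeta_s = 1 maps to delta = 0.

    Raises
    ------
    DomainError
        If zeta_s is outside (0, 1].
    """
    if not 0.0 < zeta_s <= 1.0:
        raise DomainError("zeta_s must lie in (0, 1]")
    return D / (2.0 * R_GAS * T * omega_m) * (1.0 / zeta_s - 1.0)


# ---------------------------------------------------------------------------
# implicit surface zeta_s = f(R_Cl, J_vm)


def convective_surface_residual(
    zeta_s: float,
    R_Cl: float,
    J_vm: float,
    membrane: MembraneParams,
    solutions: SolutionParams,
    T: float,
    g: float = G_STANDARD,
    mode: str = "literal",
) -> float:
    """Residual of the implicit relation between zeta_s, R_Cl and J_vm.

    Derived for the purely osmotic regime (dP = 0, C_l = 0, symmetric layer
    thickness tied to zeta_s). With

        phi_conv_1 = g*(drho/dC)*D_l^2*(Lp*sigma_m)^(-1)*(2*R*T)^(-4)*omega_m^(-3)
        phi_conv_2 = nu_l*rho_0       (rho_l = rho_h = rho_0)

    the ``"literal"`` residual reads

        J_vm*phi_conv_1*(1/z - 1)^4 * [1 + J_vm^2*(1/z - 2*sigma_m)/(2*R*T*omega_m)]
        + R_Cl*phi_conv_2 * [1 + (1 + J_vm*(1/z - 1))/(4*R*T*omega_m)]  = 0.

    The bracketed sums mix dimensions (they add pure numbers to flux-scaled
    terms); the relation is nevertheless evaluated verbatim. The
    ``"reconstructed"`` mode instead rebuilds the residual from the lower
    layer's quartic thickness balance with the same substitutions
    (delta_l from zeta_s, dpi from J_vm, C_l = 0); it is dimensionally
    consistent but is this package's own derivation, not the canonical form.
    """
    if not 0.0 < zeta_s <= 1.0:
        raise DomainError("zeta_s must lie in (0, 1]")
    RT = R_GAS * T
    Lp, sm, wm = membrane.Lp, membrane.sigma_m, membrane.omega_m
    Dl = solutions.D_l
    inv = 1.0 / zeta_s
    if mode == "literal":
        phi1 = g * solutions.drho_dC * Dl**2 / (Lp * sm) / (2.0 * RT) ** 4 / wm**3
        phi2 = solutions.nu_l * solutions.rho_l
        term1 = (
            J_vm
            * phi1
            * (inv - 1.0) ** 4
            * (1.0 + J_vm * (inv - 2.0 * sm) / (2.0 * RT * wm) * J_vm)
        )
        term2 = R_Cl * phi2 * (1.0 + (1.0 + J_vm * (inv - 1.0)) / (4.0 * RT * wm))
        return term1 + term2
    if mode == "reconstructed":
        # substitutions: delta_l = Dl/(2*RT*wm)*(1/z - 1); dpi = -J_vm/(Lp*sm*z);
        # C_l = 0 so C_h - C_l = C_h + C_l = C_h = dpi/RT
        delta_l = Dl / (2.0 * RT * wm) * (inv - 1.0)
        dpi = -J_vm / (Lp * sm * zeta_s)
        Ch = dpi / RT
        c1 = g * solutions.drho_dC * (
            zeta_s * wm * dpi + J_vm * (0.5 * Ch - zeta_s * sm * Ch)
        )
        c2 = -0.5 * J_vm * R_Cl * Dl * solutions.nu_l * solutions.rho_l
        c3 = -R_Cl * Dl**2 * solutions.nu_l * solutions.rho_l
        return c1 * delta_l**4 + c2 * delta_l + c3
    raise DomainError(f"unknown residual mode {mode!r}")


@dataclass(frozen=True)
class ZetaSurfaceResult:
    """A point on the implicit surface zeta_s = f(R_Cl, J_vm)."""

    zeta_s: float | None
    residual: float
    physical: bool
    message: str = ""


def implicit_zeta_surface(
    R_Cl: float,
    J_vm: float,
    membrane: MembraneParams,
    solutions: SolutionParams,
    T: float,
    g: float = G_STANDARD,
    mode: str = "literal",
    n_bracket: int = 400,
) -> ZetaSurfaceResult:
    """Solve the implicit relation for zeta_s in (0, 1] at given (R_Cl, J_vm).

    The residual is scanned on a grid that is logarithmic in (1/z - 1) to
    resolve the steep quartic branch near z -> 0; a sign change is refined by
    bisection (brentq). At J_vm = 0 the residual reduces to
    R_Cl*phi_conv_2*[1 + 1/(4*R*T*omega_m)], so a solution exists only at
    R_Cl = 0, where every zeta_s is neutral; the unpolarized value 1 anchors
    the surface there.

    Returns a result flagging "no solution on physical branch" when the
    residual has no sign change in (0, 1].
    """
    if J_vm > 0:
        raise DomainError("the osmotic-regime derivation assumes J_vm <= 0")
    if J_vm == 0.0:
        if R_Cl == 0.0:
            return ZetaSurfaceResult(1.0, 0.0, True, "anchored at origin")
        return ZetaSurfaceResult(
            None, math.inf, False, "no solution on physical branch (J_vm = 0)"
        )

    def f(z: float) -> float:
        return convective_surface_residual(
            z, R_Cl, J_vm, membrane, solutions, T, g, mode
        )

    # grid: 1/z - 1 from 1e-8 up to 1e10, log-spaced, plus z = 1 endpoint
    u = np.logspace(-8, 10, n_bracket)
    zs = 1.0 / (1.0 + u)
    zs = np.concatenate(([1.0], zs))
    vals = np.array([f(z) for z in zs])
    sign = np.sign(vals)
    idx = np.flatnonzero((sign[:-1] * sign[1:]) < 0)
    exact = np.flatnonzero(vals == 0.0)
    if exact.size:
        z0 = float(zs[exact[0]])
        return ZetaSurfaceResult(z0, 0.0, True)
    if idx.size == 0:
        return ZetaSurfaceResult(
            None, math.inf, False, "no solution on physical branch"
        )
    i = idx[0]
    a, b = float(zs[i + 1]), float(zs[i])  # zs is decreasing
    root = brentq(f, a, b, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    # residual certificate scaled by the dominant term magnitude
    RT = R_GAS * T
    phi2 = solutions.nu_l * solutions.rho_l
    dom = max(
        abs(R_Cl) * phi2 * (1.0 + 1.0 / (4.0 * RT * membrane.omega_m)),
        abs(f(min(1.0, root * 2.0))),
        1e-300,
    )
    resid = abs(f(root)) / dom
    return ZetaSurfaceResult(float(root), resid, True)
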