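"""Closed-form and polynomial relations for the polarization coefficient.

This module implements the Kedem-Katchalsky (K-K) flux laws, their modified
form under concentration polarization, and the family of algebraically
equivalent expressions linking the diffusive polarization coefficient
zeta_s = omega_s/omega_m to the membrane volume flux J_vm and the driving
forces dP and dpi:

* the series-resistance form from the layer permeabilities
  (``zeta_s_series``),
* boundary concentrations C_i, C_e at given flux (``boundary_concentrations``),
* the rational form zeta_s(J_vm) (``rational_coefficients`` /
  ``zeta_from_jvm``), its zero-flux limit (``zeta_zero_flux``),
* the self-consistent cubic obtained by eliminating J_vm
  (``cubic_coefficients`` / ``solve_zeta_cubic``).

Mean-concentration convention: the K-K solute equation uses the logarithmic
mean C-bar = (C_h - C_l)/ln(C_h/C_l), which for C_h/C_l -> 1 approaches the
arithmetic mean 0.5*(C_h + C_l). The steady-state layer equations and the
coefficient blocks derived from them use the arithmetic mean C-bar_s (that is
what makes the rational, cubic and brute-force routes agree identically), so
``rational_coefficients`` and ``cubic_coefficients`` default to
``cbar_mode="arithmetic"``; a ``"logmean"`` switch is provided for
sensitivity studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .errors import DomainError, PoleError, SingularLayerError
from .params import (
    Conditions,
    CubicCoefficients,
    LayerGeometry,
    MembraneParams,
    R_GAS,
    RationalCoefficients,
    SolutionParams,
    ZetaSet,
)

__all__ = [
    "log_mean_concentration",
    "mean_concentration",
    "ClassicalFluxes",
    "classical_kk_fluxes",
    "ModifiedFluxes",
    "modified_kk_fluxes",
    "zeta_s_series",
    "omega_layer",
    "omega_series",
    "boundary_concentrations",
    "jvm_membrane",
    "rational_coefficients",
    "ZetaValue",
    "zeta_from_jvm",
    "zeta_zero_flux",
    "jvm_self_consistent",
    "cubic_coefficients",
    "CubicSolution",
    "solve_zeta_cubic",
    "zeta_cubic",
]


# ---------------------------------------------------------------------------
# mean concentrations and classical fluxes


def log_mean_concentration(C_l: float, C_h: float) -> float:
    """Logarithmic mean concentration (C_h - C_l)/ln(C_h/C_l), mol m^-3.

    Continuous at C_l == C_h (returns the common value). For ratios near 1
    this is within a fraction of a percent of the arithmetic mean.

    Raises
    ------
    DomainError
        If either concentration is not strictly positive.
    """
    if C_l <= 0 or C_h <= 0:
        raise DomainError("log-mean requires strictly positive concentrations")
    if C_l == C_h:
        return float(C_l)
    return (C_h - C_l) / math.log(C_h / C_l)


def mean_concentration(C_l: float, C_h: float, mode: str = "logmean") -> float:
    """Mean concentration C-bar with a documented fallback.

    ``mode="logmean"`` returns the logarithmic mean, falling back to the
    arithmetic mean when a concentration is zero (where the log-mean is
    undefined) or the two are equal. ``mode="arithmetic"`` returns
    0.5*(C_h + C_l).
    """
    if mode == "arithmetic":
        return 0.5 * (C_h + C_l)
    if mode != "logmean":
        raise DomainError(f"unknown cbar mode {mode!r}")
    if C_l <= 0 or C_h <= 0 or C_l == C_h:
        return 0.5 * (C_h + C_l)
    return log_mean_concentration(C_l, C_h)


class ClassicalFluxes(NamedTuple):
    J_v: float  # volume flux, m s^-1
    J_s: float  # solute flux, mol m^-2 s^-1


def classical_kk_fluxes(
    membrane: MembraneParams,
    conditions: Conditions,
    cbar_mode: str = "logmean",
) -> ClassicalFluxes:
    """Classical K-K fluxes for homogeneous (well-stirred) solutions.

    J_v = Lp*(dP - sigma_m*dpi)
    J_s = omega_m*dpi + C-bar*(1 - sigma_m)*J_v
    """
    J_v = membrane.Lp * (conditions.dP - membrane.sigma_m * conditions.dpi)
    cbar = mean_concentration(conditions.C_l, conditions.C_h, cbar_mode)
    J_s = membrane.omega_m * conditions.dpi + cbar * (1.0 - membrane.sigma_m) * J_v
    return ClassicalFluxes(J_v, J_s)


class ModifiedFluxes(NamedTuple):
    J_vs: float  # volume flux through the sandwich, m s^-1
    J_ss: float  # solute flux through the sandwich, mol m^-2 s^-1
    J_ss_advective_form: float  # same flux via the force decomposition
    omega_sa: float  # advective permeability C-bar*(1-zeta_a*sigma_m)*zeta_p*Lp


def modified_kk_fluxes(
    membrane: MembraneParams,
    conditions: Conditions,
    zetas: ZetaSet,
    cbar_mode: str = "logmean",
) -> ModifiedFluxes:
    """Polarization-modified K-K fluxes.

    J_vs = zeta_p*Lp*(dP - zeta_v*sigma_m*dpi)
    J_ss = zeta_s*omega_m*dpi + C-bar*(1 - zeta_a*sigma_m)*J_vs

    ``J_ss_advective_form`` re-expresses J_ss directly in the forces,

    J_ss = [zeta_s*omega_m - omega_sa*zeta_v*sigma_m]*dpi + omega_sa*dP,

    with omega_sa = C-bar*(1 - zeta_a*sigma_m)*zeta_p*Lp; the two forms are
    algebraically identical. With all coefficients equal to 1 the classical
    fluxes are recovered exactly.
    """
    Lp, sm, wm = membrane.Lp, membrane.sigma_m, membrane.omega_m
    dP, dpi = conditions.dP, conditions.dpi
    cbar = mean_concentration(conditions.C_l, conditions.C_h, cbar_mode)

    J_vs = zetas.zeta_p * Lp * (dP - zetas.zeta_v * sm * dpi)
    adv = cbar * (1.0 - zetas.zeta_a * sm)
    J_ss = zetas.zeta_s * wm * dpi + adv * J_vs
    omega_sa = adv * zetas.zeta_p * Lp
    J_ss_2a = (
        zetas.zeta_s * wm - omega_sa * zetas.zeta_v * sm
    ) * dpi + omega_sa * dP
    return ModifiedFluxes(J_vs, J_ss, J_ss_2a, omega_sa)


# ---------------------------------------------------------------------------
# series-resistance route to zeta_s


def omega_layer(D: float, delta: float, T: float) -> float:
    """Solute permeability of an unstirred layer, omega = D/(R*T*delta).

    A zero thickness returns ``math.inf`` (a perfectly permeable,
    vanishing layer); this sentinel composes correctly in
    :func:`omega_series`.
    """
    if delta < 0:
        raise DomainError("delta must be >= 0")
    if delta == 0.0:
        return math.inf
    return D / (R_GAS * T * delta)


def omega_series(omega_m: float, omega_l: float, omega_h: float) -> float:
    """Series composition 1/omega_s = 1/omega_m + 1/omega_l + 1/omega_h.

    Infinite inputs (vanishing layers) drop out; any zero input forces
    omega_s = 0. The result never exceeds the smallest input.
    """
    omegas = (omega_m, omega_l, omega_h)
    if any(w < 0 for w in omegas):
        raise DomainError("permeabilities must be >= 0")
    if any(w == 0.0 for w in omegas):
        return 0.0
    inv = sum(0.0 if math.isinf(w) else 1.0 / w for w in omegas)
    return math.inf if inv == 0.0 else 1.0 / inv


def zeta_s_series(
    membrane: MembraneParams,
    solutions: SolutionParams,
    geometry: LayerGeometry,
    T: float,
) -> float:
    """Diffusive polarization coefficient from the series-resistance picture.

    zeta_s = D_l*D_h / [D_l*D_h + R*T*omega_m*(D_h*delta_l + D_l*delta_h)]

    Equal to omega_s/omega_m with the layer permeabilities D/(R*T*delta);
    always in (0, 1], equal to 1 only for vanishing layers (or omega_m -> 0).
    """
    Dl, Dh = solutions.D_l, solutions.D_h
    num = Dl * Dh
    den = num + R_GAS * T * membrane.omega_m * (
        Dh * geometry.delta_l + Dl * geometry.delta_h
    )
    return num / den


# ---------------------------------------------------------------------------
# boundary concentrations and membrane flux


class BoundaryConcentrations(NamedTuple):
    C_i: float  # at the membrane/h-layer boundary, mol m^-3
    C_e: float  # at the l-layer/membrane boundary, mol m^-3


def boundary_concentrations(
    membrane: MembraneParams,
    solutions: SolutionParams,
    geometry: LayerGeometry,
    conditions: Conditions,
    J_vm: float,
    zeta_s: float,
    zeta_a: float | None = None,
) -> BoundaryConcentrations:
    """Steady-state concentrations at the two membrane faces for given J_vm.

    C_i = [D_h*C_h - zeta_s*omega_m*delta_h*dpi
           + J_vm*delta_h*(zeta_a*sigma_m*Cbar_s - C_l/2)] / (D_h - J_vm*delta_h/2)
    C_e = [D_l*C_l + zeta_s*omega_m*delta_l*dpi
           + J_vm*delta_l*(C_h/2 - zeta_a*sigma_m*Cbar_s)] / (D_l + J_vm*delta_l/2)

    with Cbar_s = 0.5*(C_h + C_l). ``zeta_a`` defaults to ``zeta_s`` (the
    working assumption). A vanishing layer (delta = 0) collapses the
    corresponding face concentration onto the bulk value.

    Raises
    ------
    SingularLayerError
        If a denominator D -+ J_vm*delta/2 vanishes (advection exactly
        cancels diffusion in that layer).
    """
    if zeta_a is None:
        zeta_a = zeta_s
    sm, wm = membrane.sigma_m, membrane.omega_m
    Dl, Dh = solutions.D_l, solutions.D_h
    dl, dh = geometry.delta_l, geometry.delta_h
    Cl, Ch, dpi = conditions.C_l, conditions.C_h, conditions.dpi
    cbar_s = 0.5 * (Ch + Cl)

    den_h = Dh - 0.5 * J_vm * dh
    den_l = Dl + 0.5 * J_vm * dl
    if abs(den_h) <= 1e-14 * Dh:
        raise SingularLayerError("h")
    if abs(den_l) <= 1e-14 * Dl:
        raise SingularLayerError("l")

    C_i = (
        Dh * Ch - zeta_s * wm * dh * dpi + J_vm * dh * (zeta_a * sm * cbar_s - 0.5 * Cl)
    ) / den_h
    C_e = (
        Dl * Cl + zeta_s * wm * dl * dpi + J_vm * dl * (0.5 * Ch - zeta_a * sm * cbar_s)
    ) / den_l
    return BoundaryConcentrations(C_i, C_e)


def jvm_membrane(
    membrane: MembraneParams, dP: float, C_i: float, C_e: float, T: float
) -> float:
    """Membrane volume flux J_vm = Lp*[dP - sigma_m*R*T*(C_i - C_e)], m s^-1."""
    return membrane.Lp * (dP - membrane.sigma_m * R_GAS * T * (C_i - C_e))


# ---------------------------------------------------------------------------
# rational form zeta_s(J_vm)


def rational_coefficients(
    membrane: MembraneParams,
    solutions: SolutionParams,
    geometry: LayerGeometry,
    conditions: Conditions,
    cbar_mode: str = "arithmetic",
) -> RationalCoefficients:
    """Coefficients of zeta_s = (J^3 + phi0*J^2 + phi1*J + phi2)/(mu0*J - mu1).

    phi0 = -2*[(D_h*dl - D_l*dh) + 0.5*Lp*dl*dh*(dP + sigma_m*dpi)]/(dl*dh)
    phi1 = [2*Lp*dP*(D_h*dl - D_l*dh) - 4*D_l*D_h]/(dl*dh)
    phi2 = 4*Lp*D_l*D_h*(dP - sigma_m*dpi)/(dl*dh)
    mu0  = 4*Lp*sigma_m^2*R*T*C-bar*(D_l*dh + D_h*dl)/(dl*dh)
    mu1  = 4*Lp*sigma_m*dpi*omega_m*R*T*(D_l*dh + D_h*dl)/(dl*dh)

    The arithmetic C-bar in mu0 (default) makes this form the exact
    elimination of C_i and C_e from the steady-state layer balances; the
    log-mean alternative matches the classical-flux convention but differs
    from the brute-force steady state at large concentration ratios.
    """
    dl, dh = geometry.delta_l, geometry.delta_h
    if dl <= 0 or dh <= 0:
        raise DomainError("rational coefficients require delta_l, delta_h > 0")
    Lp, sm, wm = membrane.Lp, membrane.sigma_m, membrane.omega_m
    Dl, Dh = solutions.D_l, solutions.D_h
    dP, dpi, RT = conditions.dP, conditions.dpi, conditions.RT
    cbar = mean_concentration(conditions.C_l, conditions.C_h, cbar_mode)
    dd = dl * dh
    cross = Dl * dh + Dh * dl

    phi0 = -2.0 * ((Dh * dl - Dl * dh) + 0.5 * Lp * dd * (dP + sm * dpi)) / dd
    phi1 = (2.0 * Lp * dP * (Dh * dl - Dl * dh) - 4.0 * Dl * Dh) / dd
    phi2 = 4.0 * Lp * Dl * Dh * (dP - sm * dpi) / dd
    mu0 = 4.0 * Lp * sm**2 * RT * cbar * cross / dd
    mu1 = 4.0 * Lp * sm * dpi * wm * RT * cross / dd
    return RationalCoefficients(phi0, phi1, phi2, mu0, mu1)


class ZetaValue(NamedTuple):
    """A polarization-coefficient value with its physicality flag."""

    value: float
    physical: bool  # True iff value lies in [0, 1]


def zeta_from_jvm(
    J_vm: float,
    coeffs: RationalCoefficients,
    pole_rtol: float = 1e-12,
) -> ZetaValue:
    """Evaluate the rational form zeta_s(J_vm).

    The value is returned raw (not clamped); ``physical`` flags whether it
    lies in [0, 1].

    Raises
    ------
    PoleError
        If |mu0*J_vm - mu1| <= pole_rtol * |mu1| (or the denominator is
        exactly zero), i.e. J_vm sits at the pole J_vm* = mu1/mu0.
    """
    num, den = coeffs(J_vm)
    if abs(den) <= pole_rtol * abs(coeffs.mu1) or den == 0.0:
        raise PoleError(coeffs.pole_jvm)
    value = num / den
    return ZetaValue(value, 0.0 <= value <= 1.0)


def zeta_zero_flux(
    membrane: MembraneParams,
    solutions: SolutionParams,
    geometry: LayerGeometry,
    conditions: Conditions,
) -> float:
    """Zero-flux limit of the rational form.

    zeta_s = D_l*D_h / [omega_m*R*T*(D_l*delta_h + D_h*delta_l)]
             * (1 - dP/(sigma_m*dpi))

    It can exceed 1 for thin layers because,
    unlike the series form, its denominator omits the D_l*D_h membrane term.
    The value is not clamped.

    Raises
    ------
    DomainError
        If sigma_m*dpi == 0 (the expression is undefined).
    """
    sm = membrane.sigma_m
    dpi = conditions.dpi
    if sm * dpi == 0.0:
        raise DomainError("zeta_zero_flux requires sigma_m != 0 and dpi != 0")
    Dl, Dh = solutions.D_l, solutions.D_h
    dl, dh = geometry.delta_l, geometry.delta_h
    lead = Dl * Dh / (
        membrane.omega_m * conditions.RT * (Dl * dh + Dh * dl)
    )
    return lead * (1.0 - conditions.dP / (sm * dpi))


def jvm_self_consistent(
    membrane: MembraneParams, zeta_s: float, dP: float, dpi: float
) -> float:
    """Volume flux at given polarization: J_vm = Lp*(dP - sigma_m*zeta_s*dpi).

    With dP = 0 and dpi > 0 the flux is negative: volume flows from the
    dilute (lower) to the concentrated (upper) compartment.
    """
    return membrane.Lp * (dP - membrane.sigma_m * zeta_s * dpi)


# ---------------------------------------------------------------------------
# self-consistent cubic


def cubic_coefficients(
    membrane: MembraneParams,
    solutions: SolutionParams,
    geometry: LayerGeometry,
    conditions: Conditions,
    cbar_mode: str = "arithmetic",
) -> CubicCoefficients:
    """Coefficients of the cubic obtained by eliminating J_vm.

    Substituting J_vm = Lp*(dP - sigma_m*zeta_s*dpi) into the rational form
    yields Z1*zeta^3 + Z2*zeta^2 + Z3*zeta + Z4 = 0 with

    Z1 = Lp^3*sigma_m^3*dpi^3
    Z2 = Lp^2*sigma_m^2*[Lp*dl*dh*dpi^2*(sigma_m*dpi - 2*dP)
         + 2*dpi^2*(D_h*dl - D_l*dh)
         - 4*R*T*Cbar_s*(D_h*dl + D_l*dh)*sigma_m*dpi]/(dl*dh)
    Z3 = [Lp^3*sigma_m*dl*dh*dpi*dP^2 - 2*(D_h*dl - D_l*dh)*Lp^2*sigma_m*dpi*dP
         - 2*Lp^3*sigma_m^2*dl*dh*dP*dpi^2 - 4*D_l*D_h*Lp*sigma_m*dpi
         + 4*Lp^2*sigma_m^2*R*T*Cbar_s*(D_h*dl + D_l*dh)*dP
         - 4*Lp*sigma_m*omega_m*R*T*(D_h*dl + D_l*dh)*dpi]/(dl*dh)
    Z4 = [4*Lp*D_l*D_h*sigma_m*dpi + Lp^3*dl*dh*dP^2*sigma_m*dpi]/(dl*dh)

    Degree collapse: Z1 = 0 exactly when dpi = 0 or sigma_m = 0.
    """
    dl, dh = geometry.delta_l, geometry.delta_h
    if dl <= 0 or dh <= 0:
        raise DomainError("cubic coefficients require delta_l, delta_h > 0")
    Lp, sm, wm = membrane.Lp, membrane.sigma_m, membrane.omega_m
    Dl, Dh = solutions.D_l, solutions.D_h
    dP, dpi, RT = conditions.dP, conditions.dpi, conditions.RT
    cbar = mean_concentration(conditions.C_l, conditions.C_h, cbar_mode)
    dd = dl * dh
    cross = Dh * dl + Dl * dh

    Z1 = Lp**3 * sm**3 * dpi**3
    Z2 = (
        Lp**2
        * sm**2
        * (
            Lp * dd * dpi**2 * (sm * dpi - 2.0 * dP)
            + 2.0 * dpi**2 * (Dh * dl - Dl * dh)
            - 4.0 * RT * cbar * cross * sm * dpi
        )
        / dd
    )
    Z3 = (
        Lp**3 * sm * dd * dpi * dP**2
        - 2.0 * (Dh * dl - Dl * dh) * Lp**2 * sm * dpi * dP
        - 2.0 * Lp**3 * sm**2 * dd * dP * dpi**2
        - 4.0 * Dl * Dh * Lp * sm * dpi
        + 4.0 * Lp**2 * sm**2 * RT * cbar * cross * dP
        - 4.0 * Lp * sm * wm * RT * cross * dpi
    ) / dd
    Z4 = (4.0 * Lp * Dl * Dh * sm * dpi + Lp**3 * dd * dP**2 * sm * dpi) / dd
    return CubicCoefficients(Z1, Z2, Z3, Z4)


@dataclass(frozen=True)
class CubicSolution:
    """Roots of the self-consistent cubic with the selected physical root.

    ``real_roots`` lists all real roots (ascending); ``physical_root`` is the
    real root in [0, 1] minimizing the self-consistency defect (None when no
    real root is physical); ``physical`` mirrors that; ``degree`` is the
    effective polynomial degree after trimming negligible leading
    coefficients; ``multiplicity`` counts coincident real roots at the
    selected root.
    """

    real_roots: tuple[float, ...]
    physical_root: float | None
    physical: bool
    degree: int
    multiplicity: int
    closure_defects: tuple[float, ...] = ()


def solve_zeta_cubic(
    coeffs: CubicCoefficients,
    closure_defect: Callable[[float], float] | None = None,
    tie_break_target: float | None = None,
    physical_atol: float = 1e-9,
) -> CubicSolution:
    """Solve the cubic in zeta_s and select the physical root.

    Roots are computed from the companion matrix after trimming leading
    coefficients that are negligible relative to the largest |Zi| (the degree
    collapses when dpi = 0 or sigma_m = 0), then polished with Newton steps.
    The physical root is the real root in [0, 1] (within ``physical_atol``)
    minimizing ``closure_defect`` — by construction
    |zeta_from_jvm(jvm_self_consistent(z)) - z| — when provided; ties (or a
    missing defect function) are broken toward ``tie_break_target``
    (typically the series value) or, failing that, the smallest such root.

    Raises
    ------
    DomainError
        If all four coefficients are zero (degenerate identity).
    """
    Z = np.asarray(coeffs.as_tuple(), dtype=float)
    scale = np.max(np.abs(Z))
    if scale == 0.0:
        raise DomainError("all cubic coefficients are zero; equation is degenerate")
    trimmed = np.array(Z)
    # trim leading coefficients that vanish at the formula level
    k = 0
    while k < 3 and abs(trimmed[k]) <= 1e-14 * scale:
        k += 1
    poly = trimmed[k:]
    degree = len(poly) - 1
    if degree == 0:
        raise DomainError("cubic degenerated to a nonzero constant; no roots")
    roots = np.roots(poly)

    # Newton polish on the full cubic
    def f(z: complex) -> complex:
        return ((Z[0] * z + Z[1]) * z + Z[2]) * z + Z[3]

    def fp(z: complex) -> complex:
        return (3.0 * Z[0] * z + 2.0 * Z[1]) * z + Z[2]

    polished = []
    for r in roots:
        z = complex(r)
        for _ in range(3):
            d = fp(z)
            if d == 0:
                break
            z = z - f(z) / d
        polished.append(z)
    roots = np.asarray(polished)

    real_mask = np.abs(roots.imag) <= 1e-8 * (1.0 + np.abs(roots.real))
    real_roots = np.sort(roots.real[real_mask])
    # multiplicity bookkeeping (coincident real roots)
    mult = 1
    if len(real_roots) > 1:
        gaps = np.diff(real_roots)
        tol = 1e-9 * (1.0 + np.max(np.abs(real_roots)))
        mult = int(np.max(np.diff(np.flatnonzero(np.concatenate(([True], gaps > tol, [True]))))))

    candidates = [r for r in real_roots if -physical_atol <= r <= 1.0 + physical_atol]
    defects: list[float] = []
    physical_root: float | None = None
    if candidates:
        if closure_defect is not None:
            defects = [closure_defect(float(r)) for r in candidates]
            best = int(np.argmin(defects))
            # tie-break toward the series value when defects are indistinguishable
            if tie_break_target is not None:
                dmin = defects[best]
                tied = [
                    i
                    for i, d in enumerate(defects)
                    if d <= dmin * (1.0 + 1e-9) + 1e-300
                ]
                if len(tied) > 1:
                    best = min(tied, key=lambda i: abs(candidates[i] - tie_break_target))
        elif tie_break_target is not None:
            best = int(np.argmin([abs(r - tie_break_target) for r in candidates]))
        else:
            best = 0
        physical_root = float(min(max(candidates[best], 0.0), 1.0))

    return CubicSolution(
        real_roots=tuple(float(r) for r in real_roots),
        physical_root=physical_root,
        physical=physical_root is not None,
        degree=degree,
        multiplicity=mult,
        closure_defects=tuple(defects),
    )


def zeta_cubic(
    membrane: MembraneParams,
    solutions: SolutionParams,
    geometry: LayerGeometry,
    conditions: Conditions,
    cbar_mode: str = "arithmetic",
) -> CubicSolution:
    """Build the cubic for a full parameter set and solve it.

    Convenience wrapper: assembles :func:`cubic_coefficients`, a closure
    defect built from the rational form and the self-consistent flux, and the
    series value as tie-break target, then calls :func:`solve_zeta_cubic`.
    """
    coeffs = cubic_coefficients(membrane, solutions, geometry, conditions, cbar_mode)
    rational = rational_coefficients(membrane, solutions, geometry, conditions, cbar_mode)
    target = zeta_s_series(membrane, solutions, geometry, conditions.T)

    def defect(z: float) -> float:
        J = jvm_self_consistent(membrane, z, conditions.dP, conditions.dpi)
        try:
            back = zeta_from_jvm(J, rational).value
        except PoleError:
            return math.inf
        return abs(back - z)

    return solve_zeta_cubic(coeffs, closure_defect=defect, tie_break_target=target)
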