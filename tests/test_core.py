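"""Unit and property tests for the closed-form polarization relations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import kkpolar as kk
from kkpolar import (
    Conditions,
    LayerGeometry,
    MembraneParams,
    R_GAS,
    SolutionParams,
    ZetaSet,
)
from conftest import instances


# ---------------------------------------------------------------------------
# means and classical fluxes


@pytest.mark.parametrize(
    "C_l, C_h, expected",
    [
        (5.0, 5.0, 5.0),  # continuous limit at equal concentrations
        (1.0, math.e, math.e - 1.0),  # ln ratio = 1
    ],
)
def test_log_mean_examples(C_l, C_h, expected):
    assert kk.log_mean_concentration(C_l, C_h) == pytest.approx(expected, rel=1e-14)


def test_log_mean_close_to_arithmetic_for_near_equal():
    lm = kk.log_mean_concentration(99.0, 101.0)
    assert lm == pytest.approx(100.0, rel=1e-4)


def test_log_mean_rejects_nonpositive():
    with pytest.raises(kk.DomainError):
        kk.log_mean_concentration(0.0, 5.0)
    with pytest.raises(kk.DomainError):
        kk.log_mean_concentration(5.0, -1.0)


def test_classical_flux_force_balance(glucose):
    m = glucose.membrane
    c = Conditions(C_l=10.0, C_h=20.0, T=295.0, dP=0.0)
    balanced = Conditions(C_l=10.0, C_h=20.0, T=295.0, dP=m.sigma_m * c.dpi)
    assert kk.classical_kk_fluxes(m, balanced).J_v == pytest.approx(0.0, abs=1e-25)


def test_classical_flux_pure_hydraulic(glucose):
    m = glucose.membrane
    c = Conditions(C_l=10.0, C_h=10.0, dP=1000.0, T=295.0)  # dpi = 0
    assert kk.classical_kk_fluxes(m, c).J_v == pytest.approx(m.Lp * 1000.0, rel=1e-14)


def test_classical_fluxes_hand_evaluation(glucose):
    # glucose preset, C_l = 0 (arithmetic mean fallback), C_h = 50, dP = 0
    c = Conditions(C_l=0.0, C_h=50.0, dP=0.0, T=295.0)
    J_v, J_s = kk.classical_kk_fluxes(glucose.membrane, c)
    dpi = 8.314 * 295.0 * 50.0
    J_v_hand = -5e-12 * 0.068 * dpi
    J_s_hand = 8e-10 * dpi + 0.5 * 50.0 * (1.0 - 0.068) * J_v_hand
    assert J_v == pytest.approx(J_v_hand, rel=1e-14)
    assert J_s == pytest.approx(J_s_hand, rel=1e-14)


def test_modified_recovers_classical_with_unity_zetas(glucose, mixed_conditions):
    classical = kk.classical_kk_fluxes(glucose.membrane, mixed_conditions)
    modified = kk.modified_kk_fluxes(
        glucose.membrane, mixed_conditions, ZetaSet.uniform(1.0)
    )
    assert modified.J_vs == classical.J_v
    assert modified.J_ss == classical.J_s


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    zp=st.floats(0.05, 1.0),
    zv=st.floats(0.05, 1.0),
    zs=st.floats(0.05, 1.0),
    za=st.floats(0.05, 1.0),
    Ch=st.floats(1.0, 100.0),
    dP=st.floats(-2e3, 2e3),
)
def test_modified_eq2a_is_algebraic_identity(glucose, zp, zv, zs, za, Ch, dP):
    """The force-decomposed solute flux equals the direct form exactly."""
    c = Conditions(C_l=1.0, C_h=Ch, dP=dP, T=295.0)
    f = kk.modified_kk_fluxes(glucose.membrane, c, ZetaSet(zp, zv, zs, za))
    assert f.J_ss_advective_form == pytest.approx(f.J_ss, rel=1e-12, abs=1e-25)


def test_modified_all_transport_suppressed(glucose):
    """zeta_s = 0 with a vanishing volume flux leaves no solute flux."""
    m = glucose.membrane
    zetas = ZetaSet(zeta_p=1.0, zeta_v=1.0, zeta_s=0.0, zeta_a=0.5)
    c = Conditions(C_l=10.0, C_h=20.0, T=295.0, dP=0.0)
    # choose dP so that J_vs = 0: dP = zeta_v*sigma_m*dpi
    c = Conditions(C_l=10.0, C_h=20.0, T=295.0, dP=zetas.zeta_v * m.sigma_m * c.dpi)
    f = kk.modified_kk_fluxes(m, c, zetas)
    assert f.J_vs == pytest.approx(0.0, abs=1e-25)
    assert f.J_ss == pytest.approx(0.0, abs=1e-25)


# ---------------------------------------------------------------------------
# series-resistance route


def test_zeta_series_no_layers_means_no_polarization(glucose):
    z = kk.zeta_s_series(
        glucose.membrane, glucose.solutions, LayerGeometry(0.0, 0.0), 295.0
    )
    assert z == 1.0


def test_zeta_series_vanishing_membrane_permeability(glucose, geometry):
    m = MembraneParams(Lp=glucose.membrane.Lp, sigma_m=0.068, omega_m=1e-30)
    z = kk.zeta_s_series(m, glucose.solutions, geometry, 295.0)
    assert z == pytest.approx(1.0, rel=1e-12)


def test_zeta_series_equals_series_resistance_composition():
    """zeta_s == omega_s/omega_m with layer permeabilities D/(R*T*delta)."""
    for inst in instances(50):
        m, s, g, c, _ = inst
        w_l = kk.omega_layer(s.D_l, g.delta_l, c.T)
        w_h = kk.omega_layer(s.D_h, g.delta_h, c.T)
        w_s = kk.omega_series(m.omega_m, w_l, w_h)
        assert kk.zeta_s_series(m, s, g, c.T) == pytest.approx(
            w_s / m.omega_m, rel=1e-12
        )


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    d1=st.floats(1e-5, 1e-3),
    d2=st.floats(1e-5, 1e-3),
    factor=st.floats(1.01, 10.0),
)
def test_zeta_series_strictly_decreasing_in_thickness(glucose, d1, d2, factor):
    m, s = glucose.membrane, glucose.solutions
    base = kk.zeta_s_series(m, s, LayerGeometry(d1, d2), 295.0)
    thicker_l = kk.zeta_s_series(m, s, LayerGeometry(d1 * factor, d2), 295.0)
    thicker_h = kk.zeta_s_series(m, s, LayerGeometry(d1, d2 * factor), 295.0)
    assert 0.0 < base <= 1.0
    assert thicker_l < base and thicker_h < base
    leakier = MembraneParams(m.Lp, m.sigma_m, m.omega_m * factor)
    assert kk.zeta_s_series(leakier, s, LayerGeometry(d1, d2), 295.0) < base


def test_omega_layer_substitution_and_scaling():
    T = 2500.0 / R_GAS  # chosen so R*T = 2500
    assert kk.omega_layer(1e-9, 1e-4, T) == pytest.approx(4e-9, rel=1e-14)
    assert kk.omega_layer(1e-9, 2e-4, T) == pytest.approx(2e-9, rel=1e-14)
    # glucose preset arithmetic
    assert kk.omega_layer(0.69e-9, 1e-3, 295.0) == pytest.approx(
        0.69e-9 / (8.314 * 295.0 * 1e-3), rel=1e-14
    )
    assert math.isinf(kk.omega_layer(1e-9, 0.0, 295.0))
    with pytest.raises(kk.DomainError):
        kk.omega_layer(1e-9, -1e-4, 295.0)


def test_omega_series_composition():
    assert kk.omega_series(3e-10, math.inf, math.inf) == 3e-10
    assert kk.omega_series(6e-10, 6e-10, 6e-10) == pytest.approx(2e-10, rel=1e-14)
    assert kk.omega_series(3e-10, 0.0, 1e-10) == 0.0
    w = kk.omega_series(3e-10, 5e-10, 7e-10)
    assert w <= 3e-10


# ---------------------------------------------------------------------------
# boundary concentrations and membrane flux


def test_boundary_collapse_with_vanishing_layer(glucose, osmotic_conditions):
    m, s, c = glucose.membrane, glucose.solutions, osmotic_conditions
    z = 0.5
    C_i, C_e = kk.boundary_concentrations(
        m, s, LayerGeometry(5e-4, 0.0), c, J_vm=-1e-8, zeta_s=z
    )
    assert C_i == pytest.approx(c.C_h, rel=1e-14)
    C_i, C_e = kk.boundary_concentrations(
        m, s, LayerGeometry(0.0, 5e-4), c, J_vm=-1e-8, zeta_s=z
    )
    assert C_e == pytest.approx(c.C_l, rel=1e-14)


def test_boundary_no_gradients_no_polarization(glucose, geometry):
    c = Conditions(C_l=10.0, C_h=10.0, dP=0.0, T=295.0)
    C_i, C_e = kk.boundary_concentrations(
        glucose.membrane, glucose.solutions, geometry, c, J_vm=0.0, zeta_s=0.5
    )
    assert C_i == pytest.approx(10.0, rel=1e-14)
    assert C_e == pytest.approx(10.0, rel=1e-14)


def test_boundary_zero_flux_polarized_force_identity():
    """At J_vm = 0 with the series zeta, R*T*(C_i - C_e) = zeta_s * dpi."""
    for inst in instances(50):
        m, s, g, c, _ = inst
        if g.delta_l == 0 or g.delta_h == 0:
            continue
        z = kk.zeta_s_series(m, s, g, c.T)
        C_i, C_e = kk.boundary_concentrations(m, s, g, c, J_vm=0.0, zeta_s=z)
        assert c.RT * (C_i - C_e) == pytest.approx(
            z * c.dpi, rel=1e-10, abs=1e-12
        )


def test_boundary_zero_flux_identity_symbolic():
    """The J_vm = 0 identity holds as an exact algebraic statement."""
    import sympy as sp

    Dl, Dh, dl, dh, wm, RT, Cl, Ch = sp.symbols(
        "Dl Dh dl dh wm RT Cl Ch", positive=True
    )
    dpi = RT * (Ch - Cl)
    z = Dl * Dh / (Dl * Dh + RT * wm * (Dh * dl + Dl * dh))
    C_i = (Dh * Ch - z * wm * dh * dpi) / Dh
    C_e = (Dl * Cl + z * wm * dl * dpi) / Dl
    assert sp.simplify(RT * (C_i - C_e) - z * dpi) == 0


def test_boundary_singular_layer_names_offender(glucose, osmotic_conditions):
    s = glucose.solutions
    # J_vm chosen so D_h - J_vm*delta_h/2 = 0
    delta_h = 5e-4
    J = 2.0 * s.D_h / delta_h
    with pytest.raises(kk.SingularLayerError) as err:
        kk.boundary_concentrations(
            glucose.membrane, s, LayerGeometry(5e-4, delta_h),
            osmotic_conditions, J_vm=J, zeta_s=0.5,
        )
    assert err.value.layer == "h"


def test_jvm_membrane_balance_and_nonselective(glucose):
    m = glucose.membrane
    C_i, C_e, T = 30.0, 20.0, 295.0
    dP_star = m.sigma_m * R_GAS * T * (C_i - C_e)
    assert kk.jvm_membrane(m, dP_star, C_i, C_e, T) == pytest.approx(0.0, abs=1e-25)
    open_m = MembraneParams(m.Lp, 0.0, m.omega_m)
    assert kk.jvm_membrane(open_m, 1234.0, C_i, C_e, T) == pytest.approx(
        m.Lp * 1234.0, rel=1e-14
    )
    # direct substitution
    assert kk.jvm_membrane(m, 500.0, C_i, C_e, T) == pytest.approx(
        m.Lp * (500.0 - m.sigma_m * R_GAS * T * 10.0), rel=1e-14
    )


# ---------------------------------------------------------------------------
# rational form


def _symmetric_case(preset, delta=5e-4):
    c = Conditions(C_l=5.0, C_h=40.0, dP=600.0, T=295.0)
    g = LayerGeometry(delta, delta)
    return preset.membrane, preset.solutions, g, c


def test_rational_symmetric_reduction_numeric(glucose):
    """Equal layers and diffusivities reduce to the symmetric coefficient block."""
    m, s, g, c = _symmetric_case(glucose)
    delta, D = g.delta_l, s.D_l
    rc = kk.rational_coefficients(m, s, g, c)
    cbar = 0.5 * (c.C_h + c.C_l)
    assert rc.phi0 == pytest.approx(-m.Lp * (c.dP + m.sigma_m * c.dpi), rel=1e-13)
    assert rc.phi1 == pytest.approx(-4.0 * D**2 / delta**2, rel=1e-13)
    assert rc.phi2 == pytest.approx(
        4.0 * m.Lp * D**2 / delta**2 * (c.dP - m.sigma_m * c.dpi), rel=1e-13
    )
    assert rc.mu0 == pytest.approx(
        8.0 * m.Lp * m.sigma_m**2 * c.RT * cbar * D / delta, rel=1e-13
    )
    assert rc.mu1 == pytest.approx(
        8.0 * m.Lp * m.sigma_m * c.dpi * m.omega_m * c.RT * D / delta, rel=1e-13
    )


def test_rational_symmetric_reduction_symbolic():
    import sympy as sp

    Lp, sm, wm, RT, dP, dpi, D, d, cbar = sp.symbols(
        "Lp sm wm RT dP dpi D d cbar", positive=True
    )
    dd = d * d
    cross = 2 * D * d
    phi0 = -2 * ((D * d - D * d) + sp.Rational(1, 2) * Lp * dd * (dP + sm * dpi)) / dd
    mu0 = 4 * Lp * sm**2 * RT * cbar * cross / dd
    mu1 = 4 * Lp * sm * dpi * wm * RT * cross / dd
    assert sp.simplify(phi0 + Lp * (dP + sm * dpi)) == 0
    assert sp.simplify(mu0 - 8 * Lp * sm**2 * RT * cbar * D / d) == 0
    assert sp.simplify(mu1 - 8 * Lp * sm * dpi * wm * RT * D / d) == 0


def test_rational_rejects_zero_thickness(glucose, osmotic_conditions):
    with pytest.raises(kk.DomainError):
        kk.rational_coefficients(
            glucose.membrane, glucose.solutions, LayerGeometry(0.0, 5e-4),
            osmotic_conditions,
        )


def test_zeta_from_jvm_zero_equals_zero_flux_limit():
    for inst in instances(100):
        m, s, g, c, _ = inst
        if g.delta_l == 0 or g.delta_h == 0 or m.sigma_m * c.dpi == 0:
            continue
        rc = kk.rational_coefficients(m, s, g, c)
        z0 = kk.zeta_zero_flux(m, s, g, c)
        assert kk.zeta_from_jvm(0.0, rc).value == pytest.approx(z0, rel=1e-10)


def test_zeta_from_jvm_pole(glucose, geometry, osmotic_conditions):
    rc = kk.rational_coefficients(
        glucose.membrane, glucose.solutions, geometry, osmotic_conditions
    )
    with pytest.raises(kk.PoleError) as err:
        kk.zeta_from_jvm(rc.pole_jvm, rc)
    assert err.value.pole_jvm == pytest.approx(rc.mu1 / rc.mu0, rel=1e-14)


def test_zeta_zero_flux_examples(glucose, geometry):
    m, s = glucose.membrane, glucose.solutions
    c0 = Conditions(C_l=1.0, C_h=50.0, dP=0.0, T=295.0)
    balanced = Conditions(C_l=1.0, C_h=50.0, dP=m.sigma_m * c0.dpi, T=295.0)
    assert kk.zeta_zero_flux(m, s, geometry, balanced) == pytest.approx(0.0, abs=1e-15)
    expected = s.D_l * s.D_h / (
        m.omega_m * c0.RT * (s.D_l * geometry.delta_h + s.D_h * geometry.delta_l)
    )
    assert kk.zeta_zero_flux(m, s, geometry, c0) == pytest.approx(expected, rel=1e-13)
    with pytest.raises(kk.DomainError):
        kk.zeta_zero_flux(
            m, s, geometry, Conditions(C_l=5.0, C_h=5.0, dP=100.0, T=295.0)
        )


def test_jvm_self_consistent_signs(glucose):
    m = glucose.membrane
    dpi = 1e5
    z_star = 1000.0 / (m.sigma_m * dpi)
    # zero up to rounding of the balance, tiny against the Lp*dP flux scale
    assert kk.jvm_self_consistent(m, z_star, 1000.0, dpi) == pytest.approx(
        0.0, abs=1e-22
    )
    assert kk.jvm_self_consistent(m, 0.5, 0.0, dpi) < 0  # toward concentrated side
    assert kk.jvm_self_consistent(m, 0.3, 700.0, dpi) == pytest.approx(
        m.Lp * (700.0 - m.sigma_m * 0.3 * dpi), rel=1e-14
    )


# ---------------------------------------------------------------------------
# self-consistent cubic


def test_cubic_degree_collapse_no_osmotic_force(glucose, geometry):
    c = Conditions(C_l=10.0, C_h=10.0, dP=500.0, T=295.0)  # dpi = 0
    Z = kk.cubic_coefficients(glucose.membrane, glucose.solutions, geometry, c)
    assert Z.Z1 == 0.0
    assert Z.Z2 == 0.0
    # Z3 keeps only its dP term, Z4 vanishes entirely
    m, g = glucose.membrane, geometry
    cross = glucose.solutions.D_h * g.delta_l + glucose.solutions.D_l * g.delta_h
    expected_Z3 = (
        4.0 * m.Lp**2 * m.sigma_m**2 * c.RT * 10.0 * cross * c.dP
    ) / (g.delta_l * g.delta_h)
    assert Z.Z3 == pytest.approx(expected_Z3, rel=1e-13)
    assert Z.Z4 == 0.0
    sol = kk.solve_zeta_cubic(Z)
    assert sol.degree <= 2
    assert sol.physical_root == pytest.approx(0.0, abs=1e-15)


def test_cubic_degree_collapse_nonselective(glucose, geometry, osmotic_conditions):
    m = MembraneParams(glucose.membrane.Lp, 0.0, glucose.membrane.omega_m)
    Z = kk.cubic_coefficients(m, glucose.solutions, geometry, osmotic_conditions)
    assert Z.Z1 == 0.0 and Z.Z2 == 0.0


def test_cubic_linear_case_returns_constant_root():
    from kkpolar import CubicCoefficients

    for c in (0.0, 0.25, 1.0):
        sol = kk.solve_zeta_cubic(CubicCoefficients(0.0, 0.0, 1.0, -c))
        assert sol.degree == 1
        assert sol.physical_root == pytest.approx(c, abs=1e-14)


def test_cubic_all_zero_is_degenerate():
    from kkpolar import CubicCoefficients

    with pytest.raises(kk.DomainError):
        kk.solve_zeta_cubic(CubicCoefficients(0.0, 0.0, 0.0, 0.0))


def test_cubic_root_certified_by_independent_closure_root(glucose, geometry):
    """The polynomial's physical root equals a root-find on the defining relation.

    The cubic is, by construction, the polynomial form of the closure
    zeta = zeta_from_jvm(jvm_self_consistent(zeta)); solving that scalar
    relation by bracketing,
    without ever expanding the polynomial, must give the same value and
    certify a tiny polynomial residual.
    """
    m, s = glucose.membrane, glucose.solutions
    c = Conditions(C_l=1.0, C_h=50.0, dP=300.0, T=295.0)
    rc = kk.rational_coefficients(m, s, geometry, c)

    def g(z):
        J = kk.jvm_self_consistent(m, z, c.dP, c.dpi)
        return kk.zeta_from_jvm(J, rc).value - z

    z_star = brentq(g, 1e-6, 1.0, xtol=1e-15)
    Z = kk.cubic_coefficients(m, s, geometry, c)
    z_max = max(abs(v) for v in Z.as_tuple())
    assert abs(Z(z_star)) < 1e-6 * z_max
    sol = kk.zeta_cubic(m, s, geometry, c)
    assert sol.physical_root == pytest.approx(z_star, rel=1e-8)


def test_cubic_roots_match_polynomial_oracle(glucose, geometry):
    """All real roots agree with an independent high-precision polynomial solve."""
    import sympy as sp

    m, s = glucose.membrane, glucose.solutions
    cases = [
        Conditions(C_l=1.0, C_h=50.0, dP=300.0, T=295.0),
        Conditions(C_l=5.0, C_h=30.0, dP=-800.0, T=295.0),
        Conditions(C_l=10.0, C_h=10.0, dP=500.0, T=295.0),  # collapsed degree
    ]
    x = sp.symbols("x")
    for c in cases:
        Z = kk.cubic_coefficients(m, s, geometry, c)
        sol = kk.solve_zeta_cubic(Z)
        poly = sp.Poly(
            Z.Z1 * x**3 + Z.Z2 * x**2 + Z.Z3 * x + Z.Z4, x
        )
        expected = sorted(float(r) for r in poly.nroots() if abs(sp.im(r)) < 1e-12)
        assert len(sol.real_roots) == len(expected)
        for got, want in zip(sol.real_roots, expected):
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


def test_triangle_closure_over_random_instances():
    """zeta_from_jvm(jvm_self_consistent(zeta*)) == zeta* for the physical root."""
    checked = 0
    for inst in instances(60):
        m, s, g, c, _ = inst
        if m.sigma_m * c.dpi == 0:
            continue
        try:
            sol = kk.zeta_cubic(m, s, g, c)
        except kk.DomainError:
            continue
        if sol.physical_root is None:
            continue
        rc = kk.rational_coefficients(m, s, g, c)
        J = kk.jvm_self_consistent(m, sol.physical_root, c.dP, c.dpi)
        back = kk.zeta_from_jvm(J, rc).value
        assert back == pytest.approx(sol.physical_root, rel=1e-8)
        checked += 1
    assert checked >= 40


# ---------------------------------------------------------------------------
# type invariants


def test_type_invariants_rejected():
    with pytest.raises(kk.DomainError):
        MembraneParams(Lp=-1e-12, sigma_m=0.5, omega_m=1e-10)
    with pytest.raises(kk.DomainError):
        MembraneParams(Lp=1e-12, sigma_m=1.5, omega_m=1e-10)
    with pytest.raises(kk.DomainError):
        SolutionParams(
            D_l=-1e-9, D_h=1e-9, rho_l=998.0, rho_h=998.0,
            nu_l=1e-6, nu_h=1e-6, drho_dC=0.06,
        )
    with pytest.raises(kk.DomainError):
        Conditions(C_l=-1.0, C_h=5.0)
    with pytest.raises(kk.DomainError):
        LayerGeometry(-1e-4, 1e-4)
    # negative density slope is allowed (ethanol)
    SolutionParams(
        D_l=1e-9, D_h=1e-9, rho_l=998.0, rho_h=998.0,
        nu_l=1e-6, nu_h=1e-6, drho_dC=-9e-3,
    )
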