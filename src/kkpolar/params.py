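"""Domain types for the single-membrane system with concentration boundary layers.

The system is a horizontal selective membrane M separating two compartments of
the same aqueous non-electrolyte solution. The compartment above the membrane
holds the higher concentration C_h at pressure P_h; the one below holds C_l at
P_l. Unstirred concentration boundary layers (CBLs) of thicknesses delta_l and
delta_h flank the membrane and act as non-selective pseudo-membranes in series
with it.

Sign conventions
----------------
* dP = P_h - P_l  (hydrostatic driving force, Pa)
* dpi = R*T*(C_h - C_l)  (osmotic driving force, van 't Hoff, Pa)
* Positive solute flux runs from the h side to the l side.
* Negative volume flux J_vm means volume flows l -> h (pure osmosis at dP=0).

All quantities are strict SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Default thermodynamic temperature, K (explicit everywhere, overridable).
T_DEFAULT = 295.0


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DomainError(msg)


@dataclass(frozen=True)
class MembraneParams:
    """Transport coefficients of the selective membrane.

    Parameters
    ----------
    Lp : float
        Hydraulic permeability, m^3 N^-1 s^-1. Volume flux per unit net
        pressure force.
    sigma_m : float
        Reflection coefficient, dimensionless in [0, 1]. 1 = ideally
        semipermeable, 0 = non-selective.
    omega_m : float
        Solute (diffusive) permeability, mol N^-1 s^-1. Solute flux per unit
        osmotic pressure difference at zero volume flux.
    """

    Lp: float
    sigma_m: float
    omega_m: float

    def __post_init__(self) -> None:
        _require(self.Lp > 0, "Lp must be > 0")
        _require(0.0 <= self.sigma_m <= 1.0, "sigma_m must lie in [0, 1]")
        _require(self.omega_m > 0, "omega_m must be > 0")


@dataclass(frozen=True)
class SolutionParams:
    """Per-side solute/solvent properties of the bathing solutions.

    Parameters
    ----------
    D_l, D_h : float
        Solute diffusion coefficients in the lower/upper boundary layer,
        m^2 s^-1.
    rho_l, rho_h : float
        Mass densities, kg m^-3.
    nu_l, nu_h : float
        Kinematic viscosities, m^2 s^-1.
    drho_dC : float
        Density-concentration slope d(rho)/dC, kg mol^-1. May be negative
        (ethanol lowers the density of water).
    """

    D_l: float
    D_h: float
    rho_l: float
    rho_h: float
    nu_l: float
    nu_h: float
    drho_dC: float

    def __post_init__(self) -> None:
        for name in ("D_l", "D_h", "rho_l", "rho_h", "nu_l", "nu_h"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")

    def D(self, side: str) -> float:
        return {"l": self.D_l, "h": self.D_h}[side]

    def rho(self, side: str) -> float:
        return {"l": self.rho_l, "h": self.rho_h}[side]

    def nu(self, side: str) -> float:
        return {"l": self.nu_l, "h": self.nu_h}[side]


@dataclass(frozen=True)
class Conditions:
    """Bulk concentrations, pressure difference and temperature.

    dP = P_h - P_l in Pa; the derived osmotic force is
    dpi = R*T*(C_h - C_l) (sign follows the concentrations).
    """

    C_l: float
    C_h: float
    dP: float = 0.0
    T: float = T_DEFAULT

    def __post_init__(self) -> None:
        _require(self.C_l >= 0, "C_l must be >= 0")
        _require(self.C_h >= 0, "C_h must be >= 0")
        _require(self.T > 0, "T must be > 0")

    @property
    def RT(self) -> float:
        """R*T, J mol^-1."""
        return R_GAS * self.T

    @property
    def dpi(self) -> float:
        """Osmotic pressure difference R*T*(C_h - C_l), Pa."""
        return self.RT * (self.C_h - self.C_l)


@dataclass(frozen=True)
class LayerGeometry:
    """Concentration-boundary-layer thicknesses delta_l and delta_h, m."""

    delta_l: float
    delta_h: float

    def __post_init__(self) -> None:
        _require(self.delta_l >= 0, "delta_l must be >= 0")
        _require(self.delta_h >= 0, "delta_h must be >= 0")

    def delta(self, side: str) -> float:
        return {"l": self.delta_l, "h": self.delta_h}[side]


@dataclass(frozen=True)
class ZetaSet:
    """The four concentration polarization coefficients.

    zeta_p = Lps/Lp (hydraulic), zeta_v = sigma_s/sigma_m (osmotic),
    zeta_s = omega_s/omega_m (diffusive), zeta_a = sigma_sa/sigma_m
    (advective). All equal to 1 means no polarization. Under the model's
    working assumptions zeta_a = zeta_s and zeta_p = 1.
    """

    zeta_p: float = 1.0
    zeta_v: float = 1.0
    zeta_s: float = 1.0
    zeta_a: float = 1.0

    @classmethod
    def uniform(cls, value: float = 1.0) -> "ZetaSet":
        return cls(value, value, value, value)

    @classmethod
    def diffusive(cls, zeta_s: float) -> "ZetaSet":
        """zeta_p = zeta_v = 1 and zeta_a = zeta_s (the working assumption)."""
        return cls(1.0, 1.0, zeta_s, zeta_s)

    @property
    def physical(self) -> bool:
        """True when every coefficient lies in [0, 1]."""
        return all(
            0.0 <= z <= 1.0
            for z in (self.zeta_p, self.zeta_v, self.zeta_s, self.zeta_a)
        )


@dataclass(frozen=True)
class RationalCoefficients:
    """Coefficients of the rational form zeta_s(J_vm).

    zeta_s = (J^3 + phi0*J^2 + phi1*J + phi2) / (mu0*J - mu1), SI units
    (numerator and denominator both m^3 s^-3).
    """

    phi0: float
    phi1: float
    phi2: float
    mu0: float
    mu1: float

    @property
    def pole_jvm(self) -> float:
        """Pole location J_vm* = mu1/mu0, m s^-1 (inf if mu0 == 0)."""
        if self.mu0 == 0.0:
            return math.inf
        return self.mu1 / self.mu0

    def __call__(self, J_vm: float) -> tuple[float, float]:
        """Return (numerator, denominator) at J_vm."""
        num = ((J_vm + self.phi0) * J_vm + self.phi1) * J_vm + self.phi2
        den = self.mu0 * J_vm - self.mu1
        return num, den


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients Z1..Z4 of the cubic Z1*z^3 + Z2*z^2 + Z3*z + Z4 = 0 in zeta_s."""

    Z1: float
    Z2: float
    Z3: float
    Z4: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.Z1, self.Z2, self.Z3, self.Z4)

    def __call__(self, zeta: float) -> float:
        """Evaluate the cubic at zeta."""
        return ((self.Z1 * zeta + self.Z2) * zeta + self.Z3) * zeta + self.Z4


@dataclass(frozen=True)
class SteadyState:
    """Solved steady state of the layer/membrane/layer sandwich.

    C_e and C_i are the concentrations at the l-layer/membrane and
    membrane/h-layer boundaries; J_vm the membrane volume flux; J_ss the
    system solute flux; dpi_m = R*T*(C_i - C_e) the polarized osmotic force
    across the bare membrane; residual the max normalized defect of the
    solved equations. Bulk concentrations are echoed so the mean
    concentrations are derivable.
    """

    C_e: float
    C_i: float
    J_vm: float
    J_ss: float
    zeta_s: float
    dpi_m: float
    residual: float
    C_l: float = float("nan")
    C_h: float = float("nan")

    @property
    def cbar_l(self) -> float:
        """Mean concentration of the lower layer, 0.5*(C_e + C_l)."""
        return 0.5 * (self.C_e + self.C_l)

    @property
    def cbar_h(self) -> float:
        """Mean concentration of the upper layer, 0.5*(C_h + C_i)."""
        return 0.5 * (self.C_h + self.C_i)

    @property
    def cbar_s(self) -> float:
        """Mean concentration of the whole system, 0.5*(C_h + C_l)."""
        return 0.5 * (self.C_h + self.C_l)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for the steady-state solver."""

    max_iter: int = 500
    tol: float = 1e-12
    damping: float = 0.5
    seed: int = 0
    n_restarts: int = 8

    def __post_init__(self) -> None:
        _require(self.tol > 0, "tol must be > 0")
        _require(0.0 < self.damping <= 1.0, "damping must lie in (0, 1]")
        _require(self.max_iter >= 1, "max_iter must be >= 1")


@dataclass(frozen=True)
class QuarticCoefficients:
    """Coefficients of the thickness balance c1*delta^4 + c2*delta + c3 = 0.

    ``side`` records which layer the balance belongs to: the coefficients are
    the (alpha1, alpha2, alpha3) triple for the lower layer (side "l") or the
    (beta1, beta2, beta3) triple for the upper layer (side "h"). Whenever the
    layer's Rayleigh number is positive, c3 < 0.
    """

    side: str
    c1: float
    c2: float
    c3: float

    def __post_init__(self) -> None:
        _require(self.side in ("l", "h"), "side must be 'l' or 'h'")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.c1, self.c2, self.c3)

    def __call__(self, delta: float) -> float:
        return self.c1 * delta**4 + self.c2 * delta + self.c3
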