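"""Packaged parameter sets and a seeded random-instance generator.

Two presets describe the Nephrophan cellulose dialysis membrane bathed in
dilute aqueous solutions of glucose or ethanol. Every numeric field carries a
provenance note: ``[PUBLISHED]`` values are transcribed from the published
characterization of that membrane/solute pair, ``[PACKAGE-DEFAULT]``
values (boundary-layer thicknesses, temperature) are this package's
documented defaults.

Density and viscosity of the mixed upper solution follow the dilute linear
expansions

    rho_h = rho_l * (1 + alpha_density_1*C_1h + alpha_density_2*C_2h)
    nu_h  = nu_l  * (1 + gamma_visc_1*C_1h  + gamma_visc_2*C_2h)

with index 1 = glucose, 2 = ethanol (ethanol lowers the density and slightly
raises the viscosity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping, NamedTuple

import numpy as np

from .errors import ConfigError, PresetLookupError
from .params import (
    Conditions,
    LayerGeometry,
    MembraneParams,
    R_GAS,
    SolutionParams,
    T_DEFAULT,
)

__all__ = [
    "Expansion",
    "Preset",
    "PRESET_NAMES",
    "get_preset",
    "density_viscosity_at",
    "Instance",
    "random_instance",
    "DEFAULT_RANGES",
]


@dataclass(frozen=True)
class Expansion:
    """Dilute-solution expansion coefficients of density and viscosity.

    All in m^3 mol^-1; index 1 = glucose, 2 = ethanol. (These are the density
    and viscosity expansions — distinct from the quartic thickness-balance
    coefficients, which share no symbols here.)
    """

    alpha_density_1: float = 6.01e-5
    gamma_visc_1: float = 3.95e-4
    alpha_density_2: float = -9.02e-6
    gamma_visc_2: float = 1.82e-5


@dataclass(frozen=True)
class Preset:
    """An immutable named parameter bundle with per-field provenance notes."""

    name: str
    membrane: MembraneParams
    solutions: SolutionParams
    expansion: Expansion
    delta_default: float
    delta_range: tuple[float, float]
    T_default: float
    compartment_volume_cm3: float
    notes: Mapping[str, str] = field(default_factory=dict)

    def geometry(self, delta: float | None = None) -> LayerGeometry:
        """Symmetric layer geometry at the preset's default thickness."""
        d = self.delta_default if delta is None else delta
        return LayerGeometry(d, d)


_RHO_L = 998.0  # kg m^-3
_NU_L = 1.012e-6  # m^2 s^-1
_EXPANSION = Expansion()

_COMMON_NOTES = {
    "Lp": "[PUBLISHED] Nephrophan hydraulic permeability for water",
    "rho_l": "[PUBLISHED] density of the dilute aqueous solvent",
    "nu_l": "[PUBLISHED] kinematic viscosity of the dilute aqueous solvent",
    "alpha_density_1": "[PUBLISHED] glucose density expansion",
    "gamma_visc_1": "[PUBLISHED] glucose viscosity expansion",
    "alpha_density_2": "[PUBLISHED] ethanol density expansion",
    "gamma_visc_2": "[PUBLISHED] ethanol viscosity expansion",
    "delta_default": "[PACKAGE-DEFAULT] mid-range CBL thickness",
    "delta_range": "[PACKAGE-DEFAULT] documented CBL range 1e-4..1e-3 m",
    "T_default": "[PACKAGE-DEFAULT] room temperature, always overridable",
    "compartment_volume_cm3": "[PUBLISHED] recorded as metadata only",
}


def _make_preset(name: str, sigma_m: float, omega_m: float, D: float,
                 drho_dC: float, notes: dict[str, str]) -> Preset:
    return Preset(
        name=name,
        membrane=MembraneParams(Lp=5e-12, sigma_m=sigma_m, omega_m=omega_m),
        solutions=SolutionParams(
            D_l=D, D_h=D, rho_l=_RHO_L, rho_h=_RHO_L,
            nu_l=_NU_L, nu_h=_NU_L, drho_dC=drho_dC,
        ),
        expansion=_EXPANSION,
        delta_default=5e-4,
        delta_range=(1e-4, 1e-3),
        T_default=T_DEFAULT,
        compartment_volume_cm3=200.0,
        notes=MappingProxyType({**_COMMON_NOTES, **notes}),
    )


_PRESETS: dict[str, Preset] = {
    "nephrophan-glucose": _make_preset(
        "nephrophan-glucose",
        sigma_m=0.068,
        omega_m=8e-10,
        D=0.69e-9,
        drho_dC=_RHO_L * _EXPANSION.alpha_density_1,
        notes={
            "sigma_m": "[PUBLISHED] Nephrophan reflection coefficient for glucose",
            "omega_m": "[PUBLISHED] Nephrophan solute permeability for glucose",
            "D_l": "[PUBLISHED] glucose diffusion coefficient in water",
            "D_h": "[PUBLISHED] glucose diffusion coefficient in water",
            "drho_dC": "[PUBLISHED] rho_l * alpha_density_1",
        },
    ),
    "nephrophan-ethanol": _make_preset(
        "nephrophan-ethanol",
        sigma_m=0.025,
        omega_m=14.3e-10,
        D=1.57e-9,
        drho_dC=_RHO_L * _EXPANSION.alpha_density_2,
        notes={
            "sigma_m": "[PUBLISHED] Nephrophan reflection coefficient for ethanol",
            "omega_m": "[PUBLISHED] Nephrophan solute permeability for ethanol",
            "D_l": "[PUBLISHED] ethanol diffusion coefficient in water",
            "D_h": "[PUBLISHED] ethanol diffusion coefficient in water",
            "drho_dC": "[PUBLISHED] rho_l * alpha_density_2 (negative: ethanol lowers density)",
        },
    ),
}

PRESET_NAMES: tuple[str, ...] = tuple(_PRESETS)


def get_preset(name: str) -> Preset:
    """Look up an immutable preset by name.

    Raises
    ------
    PresetLookupError
        For unknown names; the error lists the available presets.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise PresetLookupError(name, PRESET_NAMES) from None


def density_viscosity_at(
    preset: Preset, C1_h: float = 0.0, C2_h: float = 0.0
) -> tuple[float, float]:
    """Upper-compartment (rho_h, nu_h) from the dilute expansions.

    C1_h is the glucose and C2_h the ethanol concentration in mol m^-3; both
    zero returns the solvent values.
    """
    if C1_h < 0 or C2_h < 0:
        raise ConfigError("concentrations must be >= 0")
    e = preset.expansion
    rho_h = preset.solutions.rho_l * (
        1.0 + e.alpha_density_1 * C1_h + e.alpha_density_2 * C2_h
    )
    nu_h = preset.solutions.nu_l * (
        1.0 + e.gamma_visc_1 * C1_h + e.gamma_visc_2 * C2_h
    )
    return rho_h, nu_h


class Instance(NamedTuple):
    """A full randomized parameter bundle for property tests."""

    membrane: MembraneParams
    solutions: SolutionParams
    geometry: LayerGeometry
    conditions: Conditions
    preset_name: str


#: Default draw ranges (SI). dpi spans +-100 kPa, dP +-2 kPa, delta the
#: documented CBL range; membrane/diffusion parameters are multiplicative
#: perturbations of the preset values.
DEFAULT_RANGES: Mapping[str, tuple[float, float]] = MappingProxyType(
    {
        "dpi": (-100e3, 100e3),
        "dP": (-2e3, 2e3),
        "delta": (1e-4, 1e-3),
        "C_l": (0.5, 50.0),
        "perturb": (0.5, 2.0),
    }
)


def random_instance(
    seed: int,
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> Instance:
    """Draw a reproducible parameter bundle around the packaged presets.

    The same seed always yields the same bundle. Membrane and diffusion
    coefficients are the preset values scaled by log-uniform factors in
    ``ranges["perturb"]``; thicknesses, concentrations and forces are drawn
    uniformly from their ranges, with C_h back-computed from the drawn dpi
    (clipped at zero concentration).

    Raises
    ------
    ConfigError
        If a range is empty or inverted.
    """
    merged = dict(DEFAULT_RANGES)
    if ranges:
        merged.update(ranges)
    for key, (lo, hi) in merged.items():
        if not (hi >= lo):
            raise ConfigError(f"empty range for {key!r}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    name = PRESET_NAMES[int(rng.integers(len(PRESET_NAMES)))]
    p = get_preset(name)

    def scale() -> float:
        lo, hi = merged["perturb"]
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    membrane = MembraneParams(
        Lp=p.membrane.Lp * scale(),
        sigma_m=min(1.0, p.membrane.sigma_m * scale()),
        omega_m=p.membrane.omega_m * scale(),
    )
    D_l = p.solutions.D_l * scale()
    D_h = p.solutions.D_h * scale()

    T = T_DEFAULT
    C_l = float(rng.uniform(*merged["C_l"]))
    dpi = float(rng.uniform(*merged["dpi"]))
    C_h = max(0.0, C_l + dpi / (R_GAS * T))
    conditions = Conditions(
        C_l=C_l, C_h=C_h, dP=float(rng.uniform(*merged["dP"])), T=T
    )
    geometry = LayerGeometry(
        delta_l=float(rng.uniform(*merged["delta"])),
        delta_h=float(rng.uniform(*merged["delta"])),
    )
    C1 = C_h if name == "nephrophan-glucose" else 0.0
    C2 = C_h if name == "nephrophan-ethanol" else 0.0
    rho_h, nu_h = density_viscosity_at(p, C1, C2)
    solutions = replace(p.solutions, D_l=D_l, D_h=D_h, rho_h=rho_h, nu_h=nu_h)
    return Instance(membrane, solutions, geometry, conditions, name)
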