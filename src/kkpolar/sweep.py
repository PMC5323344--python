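"""Parameter-sweep engine producing tidy tables of polarization values.

A :class:`SweepSpec` names one or two axes (grid variables), a preset, an
evaluation mode, and fixed parameters. ``run_sweep`` evaluates the requested
relation at every grid point and returns a pandas DataFrame with one row per
point in deterministic (row-major) order. Failures at individual points
(poles of the rational form, missing physical roots) are flagged in the
``status`` column, never silently dropped.

Modes
-----
rational     rational form zeta_s(J_vm) at prescribed volume flux
zero-flux    the closed-form J_vm -> 0 limit expression
force-ratio  the J_vm = 0 locus zeta_s = dP/(sigma_m*dpi)
cubic        physical root of the self-consistent cubic
convective   implicit convective surface zeta_s = f(R_Cl, J_vm)
oracle       brute-force steady state of the raw coupled system

Packaged named sweeps (``named_sweep("flux-profile")`` ...
``named_sweep("convective-surface-ethanol")``) encode the standard axis
ranges used throughout the package's examples.

Axis / fixed-parameter names (SI units): ``J_vm``, ``dP``, ``dpi``, ``C_l``,
``C_h``, ``dC`` (= C_h - C_l at fixed C_l), ``delta``, ``delta_l``,
``delta_h``, ``T``, ``R_Cl``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from . import core
from .errors import ConfigError, DomainError, KKPolarError, PoleError
from .oracle import steady_state_solve
from .params import Conditions, LayerGeometry, R_GAS
from .presets import Preset, get_preset
from .rayleigh import implicit_zeta_surface

__all__ = ["Axis", "SweepSpec", "run_sweep", "named_sweep", "NAMED_SWEEPS", "SWEEP_COLUMNS"]

_MODES = ("rational", "zero-flux", "force-ratio", "cubic", "convective", "oracle")

#: Stable column order of sweep tables (axis columns precede these).
SWEEP_COLUMNS = ("zeta_s", "J_vm", "physical", "status")


class Axis(NamedTuple):
    """One grid axis: variable name, inclusive range and point count."""

    name: str
    start: float
    stop: float
    num: int

    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.num)


@dataclass(frozen=True)
class SweepSpec:
    """Declarative description of a sweep."""

    preset: str
    mode: str
    axes: tuple[Axis, ...]
    fixed: Mapping[str, float] = field(default_factory=dict)
    abs_drho: bool = False  # use |drho/dC| (destabilizing orientation) in "convective"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not self.axes:
            raise ConfigError("at least one axis is required")
        for ax in self.axes:
            if ax.num < 2:
                raise ConfigError(f"axis {ax.name!r} needs >= 2 points")
            if not (math.isfinite(ax.start) and math.isfinite(ax.stop)):
                raise ConfigError(f"axis {ax.name!r} range must be finite")


def _build_point(preset: Preset, values: Mapping[str, float]):
    """Assemble (conditions, geometry, extras) for one grid point."""
    T = values.get("T", preset.T_default)
    C_l = values.get("C_l", 0.0)
    if "C_h" in values:
        C_h = values["C_h"]
    elif "dC" in values:
        C_h = C_l + values["dC"]
    elif "dpi" in values:
        C_h = C_l + values["dpi"] / (R_GAS * T)
    else:
        C_h = C_l
    dP = values.get("dP", 0.0)
    conditions = Conditions(C_l=C_l, C_h=max(C_h, 0.0), dP=dP, T=T)
    d = values.get("delta", preset.delta_default)
    geometry = LayerGeometry(
        delta_l=values.get("delta_l", d), delta_h=values.get("delta_h", d)
    )
    return conditions, geometry


def _eval_point(preset: Preset, mode: str, values: Mapping[str, float],
                abs_drho: bool) -> dict:
    membrane, solutions = preset.membrane, preset.solutions
    conditions, geometry = _build_point(preset, values)
    out: dict = {"zeta_s": math.nan, "J_vm": math.nan, "physical": False,
                 "status": "ok"}
    if mode == "rational":
        J = values.get("J_vm", 0.0)
        coeffs = core.rational_coefficients(membrane, solutions, geometry, conditions)
        z = core.zeta_from_jvm(J, coeffs)
        out.update(zeta_s=z.value, J_vm=J, physical=z.physical)
    elif mode == "zero-flux":
        z = core.zeta_zero_flux(membrane, solutions, geometry, conditions)
        out.update(zeta_s=z, J_vm=0.0, physical=0.0 <= z <= 1.0)
    elif mode == "force-ratio":
        den = membrane.sigma_m * conditions.dpi
        if den == 0.0:
            raise DomainError("sigma_m*dpi = 0 on the J_vm = 0 locus")
        z = conditions.dP / den
        out.update(zeta_s=z, J_vm=0.0, physical=0.0 <= z <= 1.0)
    elif mode == "cubic":
        sol = core.zeta_cubic(membrane, solutions, geometry, conditions)
        if sol.physical_root is None:
            out.update(status="no-physical-root")
        else:
            J = core.jvm_self_consistent(
                membrane, sol.physical_root, conditions.dP, conditions.dpi
            )
            out.update(zeta_s=sol.physical_root, J_vm=J, physical=True)
    elif mode == "convective":
        sols = solutions
        if abs_drho:
            sols = replace(solutions, drho_dC=abs(solutions.drho_dC))
        res = implicit_zeta_surface(
            values.get("R_Cl", 0.0), values.get("J_vm", 0.0),
            membrane, sols, conditions.T,
        )
        if res.zeta_s is None:
            out.update(status="no-physical-root", J_vm=values.get("J_vm", 0.0))
        else:
            out.update(zeta_s=res.zeta_s, J_vm=values.get("J_vm", 0.0),
                       physical=res.physical)
    elif mode == "oracle":
        state = steady_state_solve(membrane, solutions, geometry, conditions)
        out.update(zeta_s=state.zeta_s, J_vm=state.J_vm, physical=True)
        out["C_e"], out["C_i"], out["residual"] = state.C_e, state.C_i, state.residual
    return out


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the sweep and return one row per grid point.

    Rows are emitted in row-major order over the axes as given. Points where
    the relation is singular (pole of the rational form) or has no physical
    root carry a non-"ok" ``status`` and NaN values instead of being dropped.
    """
    preset = get_preset(spec.preset)
    grids = np.meshgrid(*[ax.values() for ax in spec.axes], indexing="ij")
    names = [ax.name for ax in spec.axes]
    rows = []
    for idx in np.ndindex(grids[0].shape):
        point = dict(spec.fixed)
        point.update({n: float(g[idx]) for n, g in zip(names, grids)})
        row = {n: point[n] for n in names}
        try:
            row.update(_eval_point(preset, spec.mode, point, spec.abs_drho))
        except PoleError as e:
            row.update(zeta_s=math.nan, J_vm=point.get("J_vm", math.nan),
                       physical=False, status=f"pole@{e.pole_jvm:.6e}")
        except KKPolarError as e:
            row.update(zeta_s=math.nan, J_vm=math.nan, physical=False,
                       status=type(e).taxonomy)
        rows.append(row)
    df = pd.DataFrame(rows)
    ordered = names + [c for c in df.columns if c not in names]
    df = df[ordered]
    n_ok = int((df["status"] == "ok").sum())
    if n_ok == 0:
        raise ConfigError("all sweep points failed; check ranges and mode")
    return df


# ---------------------------------------------------------------------------
# packaged named sweeps


def _named_sweeps() -> dict[str, SweepSpec]:
    kPa = 1e3
    return {
        # zeta_s(J_vm) at dP = 0 for glucose; the J_vm axis straddles the
        # pole of the rational form, which the engine flags and skips
        "flux-profile": SweepSpec(
            preset="nephrophan-glucose",
            mode="rational",
            axes=(Axis("J_vm", -5e-8, 5e-8, 41),),
            fixed={"dC": 50.0, "dP": 0.0},
        ),
        # zeta_s(dC) at dP = 0 for glucose, self-consistent flux
        "concentration-profile": SweepSpec(
            preset="nephrophan-glucose",
            mode="cubic",
            axes=(Axis("dC", 1.0, 100.0, 34),),
            fixed={"dP": 0.0},
        ),
        # the J_vm = 0 sheet zeta_s = dP/(sigma_m*dpi): hyperbolic paraboloid.
        # C_l = 41 mol/m^3 keeps C_h >= 0 over the whole +-100 kPa dpi range.
        "force-locus-ethanol": SweepSpec(
            preset="nephrophan-ethanol",
            mode="force-ratio",
            axes=(Axis("dpi", -100 * kPa, 100 * kPa, 21),
                  Axis("dP", -2 * kPa, 2 * kPa, 21)),
            fixed={"C_l": 41.0},
        ),
        "force-locus-glucose": SweepSpec(
            preset="nephrophan-glucose",
            mode="force-ratio",
            axes=(Axis("dpi", -100 * kPa, 100 * kPa, 21),
                  Axis("dP", -500.0, 500.0, 21)),
            fixed={"C_l": 41.0},
        ),
        # full cubic surface for ethanol at J_vm != 0
        "force-surface-ethanol": SweepSpec(
            preset="nephrophan-ethanol",
            mode="cubic",
            axes=(Axis("dP", -150 * kPa, 0.0, 16),
                  Axis("dpi", 0.0, 100 * kPa, 11)),
            fixed={"C_l": 1.0},
        ),
        # convective surface zeta_s = f(R_Cl, J_vm), destabilizing orientation
        "convective-surface-ethanol": SweepSpec(
            preset="nephrophan-ethanol",
            mode="convective",
            axes=(Axis("R_Cl", 1.0, 100.0, 12),
                  Axis("J_vm", -1e-6, -1e-8, 12)),
            abs_drho=True,
        ),
    }


NAMED_SWEEPS: tuple[str, ...] = (
    "flux-profile",
    "concentration-profile",
    "force-locus-ethanol",
    "force-locus-glucose",
    "force-surface-ethanol",
    "convective-surface-ethanol",
)


def named_sweep(name: str) -> SweepSpec:
    """Return a packaged named sweep spec (see ``NAMED_SWEEPS``)."""
    sweeps = _named_sweeps()
    if name not in sweeps:
        raise ConfigError(
            f"unknown sweep {name!r}; available: {', '.join(NAMED_SWEEPS)}"
        )
    return sweeps[name]
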