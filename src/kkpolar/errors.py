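"""Error taxonomy for kkpolar.

Every exception raised by the library derives from :class:`KKPolarError`,
so callers (and the CLI) can distinguish numerical/domain failures from
programming errors. Each class carries a short ``taxonomy`` name that the
CLI prints on exit.
"""

from __future__ import annotations


class KKPolarError(Exception):
    """Base class for all kkpolar errors."""

    taxonomy = "error"


class DomainError(KKPolarError, ValueError):
    """An input lies outside the mathematical domain of an operation."""

    taxonomy = "domain-error"


class SingularLayerError(DomainError):
    """A boundary-layer denominator vanished (the face-concentration
    expression for C_i or C_e is singular).

    Attributes
    ----------
    layer : str
        Which layer produced the singularity, ``"l"`` (below the membrane)
        or ``"h"`` (above it).
    """

    taxonomy = "singular-layer"

    def __init__(self, layer: str, message: str | None = None):
        self.layer = layer
        super().__init__(message or f"vanishing denominator in layer '{layer}'")


class PoleError(DomainError):
    """The rational form zeta_s(J_vm) was evaluated at (or too near) its pole.

    Attributes
    ----------
    pole_jvm : float
        Location of the pole, J_vm* = mu1/mu0, in m s^-1.
    """

    taxonomy = "pole"

    def __init__(self, pole_jvm: float, message: str | None = None):
        self.pole_jvm = pole_jvm
        super().__init__(
            message or f"J_vm too close to the pole at J_vm* = {pole_jvm!r} m/s"
        )


class ConvergenceError(KKPolarError):
    """The steady-state solver failed to reach the requested tolerance.

    Attributes
    ----------
    best_residual : float
        Smallest normalized residual reached before giving up.
    """

    taxonomy = "convergence"

    def __init__(self, best_residual: float, message: str | None = None):
        self.best_residual = best_residual
        super().__init__(
            message
            or f"steady-state solve did not converge (best residual {best_residual:.3e})"
        )


class PresetLookupError(KKPolarError, KeyError):
    """An unknown preset name was requested."""

    taxonomy = "unknown-preset"

    def __init__(self, name: str, available: tuple[str, ...]):
        self.name = name
        self.available = available
        super().__init__(
            f"unknown preset {name!r}; available presets: {', '.join(available)}"
        )


class ConfigError(KKPolarError, ValueError):
    """A configuration file, sweep spec, or parameter range is invalid."""

    taxonomy = "config-error"
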