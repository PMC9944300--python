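"""Model parameters, unit conventions, and perfusion protocols.

Internal unit system: micrometres, seconds, piconewtons. Tensions are
pN/um, pressures pN/um^2 (numerically equal to Pa). Millimetres of
mercury are accepted only at the CLI/config boundary and converted on
entry. All pressures are gauge pressures relative to the external bath
pressure P_e, so P_e == 0 and the applied perfusion pressure equals the
pressure drop ``delta_p``; only pressure differences enter the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "MMHG_TO_PN_PER_UM2",
    "ModelParams",
    "Protocol",
    "ParameterError",
    "mmhg_to_pressure",
    "pressure_to_mmhg",
    "reference_params",
    "validate",
]

#: 1 mmHg in pN/um^2 (= Pa).
MMHG_TO_PN_PER_UM2 = 133.322387415


class ParameterError(ValueError):
    """A model parameter violates one of its physical invariants."""


def mmhg_to_pressure(p_mmhg: float) -> float:
    """Convert a pressure in mmHg to internal units (pN/um^2)."""
    return p_mmhg * MMHG_TO_PN_PER_UM2


def pressure_to_mmhg(p: float) -> float:
    """Convert a pressure in internal units (pN/um^2) to mmHg."""
    return p / MMHG_TO_PN_PER_UM2


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the single-cell perfusion model.

    Attributes
    ----------
    R0 : float
        Resting cell radius (um); the unperfused cell is a hemisphere.
    a : float
        Basal pore half-width (um); the bleb mouth is pinned to it.
    sigma_m : float
        Membrane entropic tension (pN/um).
    sigma_c : float
        Cortical tension from actomyosin contractility (pN/um).
    K_m : float
        Membrane area-expansion modulus (pN/um); dominates the tension
        once membrane reservoirs are exhausted.
    d : float
        Radius of the basal membrane patch over which bleb tension
        equilibrates within a vacuole lifetime (um).
    eps_star : float
        Membrane-reservoir threshold area strain (dimensionless).
    tau_c : float
        Actin turnover / myosin recruitment timescale (s).
    mu : float
        Effective dynamic viscosity of the cell interior (pN s/um^2).
    sigma_0 : float
        Total resting surface tension sigma_m + sigma_c (pN/um);
        derived, recomputed automatically when unset.

    Notes
    -----
    The taut-membrane equilibration time is taken as instantaneous
    (its limit to zero), so it has no runtime field here.
    """

    R0: float = 10.0
    a: float = 0.25
    sigma_m: float = 40.0
    sigma_c: float = 374.0
    K_m: float = 1.0e5
    d: float = 10.0
    eps_star: float = 0.5
    tau_c: float = 1.0
    mu: float = 2.5e4
    sigma_0: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sigma_0 is None:
            object.__setattr__(self, "sigma_0", self.sigma_m + self.sigma_c)

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with fields replaced; sigma_0 is rederived
        unless set explicitly."""
        if "sigma_0" not in changes and (
            "sigma_m" in changes or "sigma_c" in changes
        ):
            changes["sigma_0"] = None
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# Strain threshold admitted up to 300% for exploration of super-stretched
# states; the reference reservoir size is 50%.
_EPS_STAR_MAX = 3.0


def validate(params: ModelParams) -> ModelParams:
    """Check all physical invariants, returning ``params`` unchanged.

    Raises
    ------
    ParameterError
        Naming the violated invariant.
    """
    p = params
    positive = [
        "R0", "a", "sigma_m", "sigma_c", "K_m", "d", "tau_c", "mu", "sigma_0",
    ]
    for name in positive:
        v = getattr(p, name)
        if not np.isfinite(v) or v <= 0:
            raise ParameterError(f"{name} must be strictly positive, got {v!r}")
    if not np.isfinite(p.eps_star) or p.eps_star < 0:
        raise ParameterError(f"eps_star must be >= 0, got {p.eps_star!r}")
    if p.eps_star > _EPS_STAR_MAX:
        raise ParameterError(
            f"eps_star must be <= {_EPS_STAR_MAX} (300% strain), got {p.eps_star!r}"
        )
    if not p.a < p.d:
        raise ParameterError(f"a < d violated (a={p.a}, d={p.d})")
    if not p.a < p.R0:
        raise ParameterError(f"a < R0 violated (a={p.a}, R0={p.R0})")
    # resting cell area 3*pi*R0^2 - pi*d^2 must stay positive
    if not p.d <= p.R0 * np.sqrt(3.0):
        raise ParameterError(
            f"d <= R0*sqrt(3) violated (d={p.d}, R0={p.R0}); resting area A0 <= 0"
        )
    if not np.isclose(p.sigma_0, p.sigma_m + p.sigma_c, rtol=1e-12, atol=0.0):
        raise ParameterError(
            f"sigma_0 != sigma_m + sigma_c ({p.sigma_0} vs {p.sigma_m + p.sigma_c})"
        )
    return params


def reference_params() -> ModelParams:
    """Reference parameter set: R0 = 10 um, d = 10 um, eps* = 0.5,
    pore half-width a = 0.25 um, sigma_m = 40 and sigma_c = 374 pN/um
    (so sigma_0 = 414), K_m = 1e5 pN/um, tau_c = 1 s, mu = 2.5e4 pN s/um^2.
    """
    return validate(ModelParams())


@dataclass(frozen=True)
class Protocol:
    """Perfusion protocol: applied pressure drop and simulation horizon.

    ``schedule='constant'`` holds ``delta_p`` for all t >= 0;
    ``schedule='step_to_zero'`` removes the pressure drop at t = 0+
    (the collapse protocol), so the integrated drop is zero and
    ``delta_p`` records the preparation pressure only.
    """

    delta_p: float
    t_max: float
    schedule: str = "constant"

    def __post_init__(self) -> None:
        if self.delta_p < 0:
            raise ParameterError(f"delta_p must be >= 0, got {self.delta_p}")
        if self.t_max <= 0:
            raise ParameterError(f"t_max must be > 0, got {self.t_max}")
        if self.schedule not in ("constant", "step_to_zero"):
            raise ParameterError(f"unknown schedule {self.schedule!r}")

    @property
    def applied_delta_p(self) -> float:
        """Pressure drop actually applied during integration (t > 0)."""
        return self.delta_p if self.schedule == "constant" else 0.0
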