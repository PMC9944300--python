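"""Two-regime surface-tension law for the bleb and the cell.

Below the reservoir threshold strain eps* the tension is cortex-dominated:
the target is the constant plateau sigma_0 = sigma_m + sigma_c, approached
by exponential relaxation with the actin turnover time tau_c (the bleb's
contractile shell must be rebuilt after nucleation disrupts the cortex;
the cell cortex starts equilibrated). Above eps* the membrane reservoirs
are exhausted and further area comes from mechanical stretch: the tension
is slaved instantaneously (fast taut-membrane limit) to

    target(S) = sigma_0 + K_m * (exp((S - S*)/S*) - 1),   S* = S0 (1 + eps*),

which is continuous at S = S* and rises steeply because K_m >> sigma_0.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams

__all__ = [
    "CORTEX",
    "MEMBRANE",
    "LyticOverflowError",
    "target_tension",
    "target_bleb_tension",
    "target_cell_tension",
    "relax_tension_rhs",
    "effective_tension",
    "regime",
]

CORTEX = "cortex"
MEMBRANE = "membrane"

#: Cap on the stretch exponent (S - S*)/S*; beyond it the membrane is far
#: past any lytic tension and the model has no business being evaluated.
EXP_ARG_MAX = 50.0


class LyticOverflowError(FloatingPointError):
    """Membrane stretch exponent exceeded the lytic guard bound."""


def target_tension(S: float, S0: float, params: ModelParams) -> float:
    """Steady-state (target) tension for an area S on a patch of rest area S0."""
    S_star = S0 * (1.0 + params.eps_star)
    if S <= S_star:
        return params.sigma_0
    x = (S - S_star) / S_star
    if x > EXP_ARG_MAX:
        raise LyticOverflowError(
            f"stretch exponent {x:.3g} exceeds guard {EXP_ARG_MAX}; "
            "membrane is far beyond the lytic regime"
        )
    return params.sigma_0 + params.K_m * np.expm1(x)


def target_bleb_tension(S: float, params: ModelParams, S0: float | None = None) -> float:
    """Target bleb tension for patch area S (rest area S0 = pi d^2)."""
    if S0 is None:
        S0 = np.pi * params.d**2
    return target_tension(S, S0, params)


def target_cell_tension(A: float, params: ModelParams, A0: float) -> float:
    """Target cell tension: same functional form with cell areas A, A0."""
    return target_tension(A, A0, params)


def relax_tension_rhs(Sigma: float, target: float, tau: float) -> float:
    """Exponential relaxation rate d(Sigma)/dt = (target - Sigma)/tau.

    Closed form Sigma(t) = target + (Sigma(0) - target) exp(-t/tau)
    serves as the integrator oracle.
    """
    return (target - Sigma) / tau


def regime(eps: float, params: ModelParams) -> str:
    """Mechanical regime for a relative area strain: cortex below eps*,
    membrane above."""
    return MEMBRANE if eps > params.eps_star else CORTEX


def effective_tension(Sigma_relax: float, S: float, S0: float,
                      params: ModelParams) -> float:
    """Instantaneous tension given the relaxing cortical value and the area.

    In the cortex regime (S <= S*) the tension is the dynamical variable
    ``Sigma_relax``. Above the threshold it is slaved to the membrane
    target; the max with the relaxing value preserves continuity and
    monotone loading if the threshold is crossed before cortical
    relaxation completes (only possible for pathological tau_c).
    """
    S_star = S0 * (1.0 + params.eps_star)
    if S <= S_star:
        return Sigma_relax
    return max(Sigma_relax, target_tension(S, S0, params))
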