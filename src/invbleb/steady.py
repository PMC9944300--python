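"""Equilibria of the pressure balance, branch structure, and thresholds.

Steady states solve

    dp = 2 Sigma_bar(r) / r + 2 sigma_bar(r) / R(r),

with both tensions at their targets and R fixed by volume conservation.
Because the bleb target tension is the constant plateau sigma_0 for
S(r) <= S* and strictly increasing beyond, the residual is strictly
decreasing in r on the cortex branch and strictly increasing on the
membrane branch: each branch carries at most one root, bracketed
analytically and found by Brent's method. The two branches meet at the
reservoir-exhaustion radius r* (where S(r*) = S*), which is a
saddle-node: below dp* = F(r*) no equilibrium exists, between dp* and
dp-dagger (cortex root at r = a) there are exactly two, above only the
stable membrane-branch one survives. Membrane-branch equilibria are
stable, cortex-branch ones unstable (sign of the slaved radius-rate
derivative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import geometry, tension
from .params import ModelParams, pressure_to_mmhg

__all__ = [
    "EquilibriumRecord",
    "equilibria",
    "stability",
    "classify_stability",
    "pressure_scan",
    "delta_p_dagger",
    "nucleation_pressure_estimate",
]

_XTOL = 1e-12
_RESIDUAL_RTOL = 1e-9


@dataclass(frozen=True)
class EquilibriumRecord:
    """One root of the steady-state pressure balance."""

    delta_p: float        # pN/um^2
    delta_p_mmhg: float
    r_eq: float           # um
    R_eq: float           # um
    Sigma_eq: float       # pN/um
    sigma_eq: float       # pN/um
    branch: str           # cortex | membrane
    stable: bool
    marginal: bool
    vacuole_volume: float  # um^3
    eps_B: float
    residual: float


def _areas(r: float, params: ModelParams, n_blebs: int = 1):
    """(S, R, A) for n identical blebs of radius r on one shared patch."""
    theta = geometry.opening_angle(r, params.a)
    S = geometry.patch_area([r] * n_blebs, params.d, params.a)
    R = geometry.cell_radius([r] * n_blebs, params.a, params.R0)
    A = geometry.cell_area(R, params.d, 1)
    return S, R, A, theta


def _residual(r: float, delta_p: float, params: ModelParams,
              n_blebs: int = 1) -> float:
    """F(r) = 2 Sigma_bar/r + 2 sigma_bar/R - dp with slaved tensions."""
    S, R, A, _ = _areas(r, params, n_blebs)
    A0 = geometry.cell_area(params.R0, params.d, 1)
    Sigma_bar = tension.target_bleb_tension(S, params)
    sigma_bar = tension.target_cell_tension(A, params, A0)
    return 2.0 * Sigma_bar / r + 2.0 * sigma_bar / R - delta_p


def _radius_rate_slaved(r: float, delta_p: float, params: ModelParams,
                        n_blebs: int = 1) -> float:
    """dr/dt with tensions slaved to targets (quasi-static reduction)."""
    return -r / (4.0 * params.mu) * _residual(r, delta_p, params, n_blebs)


def reservoir_exhaustion_radius(params: ModelParams, n_blebs: int = 1) -> float:
    """Radius r* at which the patch area reaches S* = S0 (1 + eps*).

    This is where the cortex and membrane branches merge. Raises
    ``ValueError`` when no r >= a reaches S* (reservoir threshold below
    the nucleation strain a^2/d^2).
    """
    S0 = np.pi * params.d**2
    S_star = S0 * (1.0 + params.eps_star)

    def g(r):
        return geometry.patch_area([r] * n_blebs, params.d, params.a) - S_star

    if g(params.a) >= 0.0:
        raise ValueError(
            "reservoir threshold eps* is below the nucleation strain; "
            "no cortex branch exists"
        )
    hi = params.a * 2.0
    while g(hi) < 0.0:
        hi *= 2.0
        if hi > 1e6 * params.a:  # pragma: no cover
            raise RuntimeError("failed to bracket reservoir exhaustion")
    return brentq(g, params.a, hi, xtol=_XTOL)


def _overflow_radius(params: ModelParams, n_blebs: int = 1) -> float:
    """Largest admissible radius: the smaller of the radii at which the
    bleb-patch or the cell stretch exponent hits the lytic guard."""
    x_cap = 0.98 * tension.EXP_ARG_MAX
    S0 = np.pi * params.d**2
    S_cap = S0 * (1.0 + params.eps_star) * (1.0 + x_cap)

    def g_bleb(r):
        return geometry.patch_area([r] * n_blebs, params.d, params.a) - S_cap

    A0 = geometry.cell_area(params.R0, params.d, 1)
    A_cap = A0 * (1.0 + params.eps_star) * (1.0 + x_cap)
    R_cap = np.sqrt((A_cap / np.pi + params.d**2) / 3.0)

    def g_cell(r):
        return geometry.cell_radius([r] * n_blebs, params.a, params.R0) - R_cap

    def bracket(g):
        hi = params.a * 2.0
        while g(hi) < 0.0:
            hi *= 2.0
        return brentq(g, params.a, hi, xtol=_XTOL)

    return min(bracket(g_bleb), bracket(g_cell))


def classify_stability(r_eq: float, delta_p: float, params: ModelParams,
                       n_blebs: int = 1) -> str:
    """'stable' | 'unstable' | 'marginal' from the sign of the derivative
    of the slaved radius rate at the equilibrium (central difference)."""
    h = 1e-6 * r_eq
    gp = _radius_rate_slaved(r_eq + h, delta_p, params, n_blebs)
    gm = _radius_rate_slaved(r_eq - h, delta_p, params, n_blebs)
    deriv = (gp - gm) / (2.0 * h)
    # characteristic rate gradient of the individual force terms
    scale = (delta_p + 2.0 * params.sigma_0 / r_eq) / (4.0 * params.mu)
    if abs(deriv) <= 1e-6 * scale:
        return "marginal"
    return "stable" if deriv < 0.0 else "unstable"


def stability(record: "EquilibriumRecord", params: ModelParams) -> bool:
    """True iff the recorded equilibrium is linearly stable."""
    return classify_stability(record.r_eq, record.delta_p, params) == "stable"


def _make_record(r: float, delta_p: float, params: ModelParams,
                 branch: str, n_blebs: int = 1) -> EquilibriumRecord:
    S, R, A, theta = _areas(r, params, n_blebs)
    A0 = geometry.cell_area(params.R0, params.d, 1)
    Sigma_bar = tension.target_bleb_tension(S, params)
    sigma_bar = tension.target_cell_tension(A, params, A0)
    cls = classify_stability(r, delta_p, params, n_blebs)
    eps_B = (S - np.pi * params.d**2) / (np.pi * params.d**2)
    return EquilibriumRecord(
        delta_p=delta_p,
        delta_p_mmhg=pressure_to_mmhg(delta_p),
        r_eq=r,
        R_eq=R,
        Sigma_eq=Sigma_bar,
        sigma_eq=sigma_bar,
        branch=branch,
        stable=(cls == "stable"),
        marginal=(cls == "marginal"),
        vacuole_volume=geometry.cap_volume(r, theta),
        eps_B=eps_B,
        residual=_residual(r, delta_p, params, n_blebs) / max(delta_p, 1.0),
    )


def equilibria(delta_p: float, params: ModelParams,
               n_blebs: int = 1) -> list[EquilibriumRecord]:
    """All admissible roots of the steady-state balance at ``delta_p``
    (pN/um^2), sorted by radius. Empty below the nucleation threshold.

    ``n_blebs`` > 1 solves the symmetric configuration of identical
    blebs sharing one tension patch.
    """
    if delta_p < 0:
        raise ValueError("delta_p must be >= 0")
    out: list[EquilibriumRecord] = []
    try:
        r_merge = reservoir_exhaustion_radius(params, n_blebs)
    except ValueError:
        r_merge = params.a
    # cortex branch: F strictly decreasing on [a, r_merge]
    if r_merge > params.a:
        f_lo = _residual(params.a, delta_p, params, n_blebs)
        f_hi = _residual(r_merge, delta_p, params, n_blebs)
        if f_lo == 0.0:
            out.append(_make_record(params.a, delta_p, params, tension.CORTEX,
                                    n_blebs))
        elif f_lo > 0.0 >= f_hi:
            r = brentq(_residual, params.a, r_merge,
                       args=(delta_p, params, n_blebs), xtol=_XTOL)
            out.append(_make_record(r, delta_p, params, tension.CORTEX, n_blebs))
    # membrane branch: F strictly increasing on [r_merge, r_overflow]
    r_ov = _overflow_radius(params, n_blebs)
    f_lo = _residual(r_merge, delta_p, params, n_blebs)
    f_hi = _residual(r_ov, delta_p, params, n_blebs)
    if f_lo <= 0.0 < f_hi:
        r = brentq(_residual, r_merge, r_ov,
                   args=(delta_p, params, n_blebs), xtol=_XTOL)
        # avoid double-reporting the saddle-node point itself
        if not out or abs(r - out[-1].r_eq) > 1e-8 * r:
            out.append(_make_record(r, delta_p, params, tension.MEMBRANE,
                                    n_blebs))
    return sorted(out, key=lambda e: e.r_eq)


def delta_p_dagger(params: ModelParams, n_blebs: int = 1) -> float:
    """Pressure above which the cortex root exits the admissible domain
    (reaches r = a), leaving the single membrane-branch equilibrium:
    the cortex-branch residual evaluated at the pore radius,
    2 sigma_0 / a + 2 sigma_0 / R(a)."""
    return _residual(params.a, 0.0, params, n_blebs)


def delta_p_star(params: ModelParams, n_blebs: int = 1,
                 tol_mmhg: float = 1e-3) -> float:
    """Smallest pressure with any equilibrium, located by bisection on
    solution-set emptiness to ``tol_mmhg`` (the saddle-node pressure)."""
    from .params import mmhg_to_pressure

    lo, hi = 0.0, delta_p_dagger(params, n_blebs)
    if equilibria(lo, params, n_blebs):
        return lo
    tol = mmhg_to_pressure(tol_mmhg)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if equilibria(mid, params, n_blebs):
            hi = mid
        else:
            lo = mid
    return hi


def pressure_scan(params: ModelParams, delta_p_grid) -> tuple[
        dict[float, list[EquilibriumRecord]], float, float]:
    """Equilibria across a pressure grid plus the two thresholds.

    Returns (records per grid pressure, dp*, dp-dagger), pressures in
    pN/um^2. dp* is refined by bisection to 1e-3 mmHg; dp-dagger is the
    closed-form cortex-root-at-a value.
    """
    grid = np.asarray(delta_p_grid, dtype=float)
    if grid.size and (np.any(np.diff(grid) <= 0) or np.any(grid < 0)):
        raise ValueError("delta_p_grid must be positive and strictly increasing")
    records = {float(dp): equilibria(float(dp), params) for dp in grid}
    return records, delta_p_star(params), delta_p_dagger(params)


def nucleation_pressure_estimate(params: ModelParams,
                                 n_blebs: int = 1) -> float:
    """Closed-form nucleation-threshold estimate 2 sigma_0 (R + r)/(R r)
    evaluated at the reservoir-exhaustion geometry (r with S(r) = S*,
    R from volume conservation at that r)."""
    r = reservoir_exhaustion_radius(params, n_blebs)
    R = geometry.cell_radius([r] * n_blebs, params.a, params.R0)
    return 2.0 * params.sigma_0 * (R + r) / (R * r)
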