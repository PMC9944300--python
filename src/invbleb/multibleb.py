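"""Multiple competing vacuoles: shared-patch coupling and Ostwald ripening.

Blebs nucleated within one tension-equilibration patch (closer than d)
share a single stretched area S, hence a single membrane target tension:
once the shared reservoir is exhausted they compete for stretchable
membrane. Near the symmetric configuration this competition is an
Ostwald-ripening instability — the larger vacuole grows at the expense
of the smaller, which deflates to the pore radius. Blebs on separate
patches are fully independent and reproduce single-bleb behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry, tension
from .dynamics import (NOT_REACHED, PatchAssignment, Trajectory, _integrate,
                       time_to_steady)
from .params import ModelParams, Protocol
from .steady import delta_p_star, equilibria

__all__ = [
    "CoarseningResult",
    "simulate_multi",
    "coarsening_run",
    "ripening_field",
    "shared_threshold_shift",
]


@dataclass(frozen=True)
class CoarseningResult:
    """Outcome of a two-bleb competition run."""

    trajectory: Trajectory
    winner: int | None            # index of the bleb at steady state
    survivor_count: int
    symmetry_breaking_time: float  # minutes; NaN if never breaks 10%
    collapse_times: dict[int, float]


def simulate_multi(params: ModelParams, protocol: Protocol,
                   inits, assignment: PatchAssignment) -> Trajectory:
    """Integrate N blebs under the given patch assignment.

    Each bleb carries its own radius and relaxing cortical tension;
    shared-patch blebs see one stretched area and one membrane target.
    A bleb reaching r = a is frozen there, its cap removed from the
    shared area and the conserved volume, and the rest continue.
    """
    return _integrate(params, protocol, list(inits), assignment)


def _symmetry_breaking_time(traj: Trajectory, threshold: float = 0.10) -> float:
    rel = np.abs(traj.r[:, 0] - traj.r[:, 1]) / np.maximum(
        traj.r[:, 0], traj.r[:, 1])
    idx = np.flatnonzero(rel > threshold)
    return float(traj.t[idx[0]] / 60.0) if idx.size else NOT_REACHED


def coarsening_run(params: ModelParams, protocol: Protocol,
                   r1: float, r2: float,
                   Sigma0: float | None = None,
                   shared: bool = True,
                   steady_rtol: float = 0.01) -> CoarseningResult:
    """Two-bleb competition run with winner/survivor bookkeeping.

    The winner is the bleb (if any) that ends within ``steady_rtol`` of
    the appropriate stable equilibrium radius (single-bleb branch, since
    the loser has collapsed by then).
    """
    if Sigma0 is None:
        Sigma0 = params.sigma_m
    assignment = (PatchAssignment.shared(2) if shared
                  else PatchAssignment.independent(2))
    traj = simulate_multi(params, protocol, [(r1, Sigma0), (r2, Sigma0)],
                          assignment)
    collapse_times = {i: t / 60.0 for i, t in traj.collapse_times().items()}
    survivors = [i for i in range(2) if i not in collapse_times]
    winner = None
    stable = [e for e in equilibria(protocol.applied_delta_p, params)
              if e.stable]
    if stable:
        r_star = stable[-1].r_eq
        final = traj.final_radii()
        for i in survivors:
            if abs(final[i] - r_star) <= steady_rtol * r_star:
                winner = i
                break
    return CoarseningResult(
        trajectory=traj,
        winner=winner,
        survivor_count=len(survivors),
        symmetry_breaking_time=_symmetry_breaking_time(traj),
        collapse_times=collapse_times,
    )


def ripening_field(params: ModelParams, delta_p: float, r_grid) -> np.ndarray:
    """Quasi-static growth-rate field dr1/dt over a (r1, r2) grid.

    Both tensions are slaved to the shared-patch target (Sigma_1 =
    Sigma_2 = Sigma_bar, sigma = sigma_bar), the regime of the ripening
    phase portrait. Entry [i, j] is dr1/dt at r1 = r_grid[i],
    r2 = r_grid[j]; by index symmetry it also equals dr2/dt at the
    transposed point.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(r_grid < params.a):
        raise ValueError("grid radii must be >= a")
    S0 = np.pi * params.d**2
    A0 = geometry.cell_area(params.R0, params.d, 1)
    out = np.empty((r_grid.size, r_grid.size))
    for i, r1 in enumerate(r_grid):
        for j, r2 in enumerate(r_grid):
            S = geometry.patch_area([r1, r2], params.d, params.a)
            R = geometry.cell_radius([r1, r2], params.a, params.R0)
            A = geometry.cell_area(R, params.d, 1)
            Sigma = tension.target_bleb_tension(S, params)
            sigma = tension.target_cell_tension(A, params, A0)
            P = 2.0 * sigma / R
            out[i, j] = r1 / (4.0 * params.mu) * (delta_p - P - 2.0 * Sigma / r1)
    return out


def shared_threshold_shift(params: ModelParams,
                           delta_p: float) -> tuple[float, float | None]:
    """Nucleation threshold and symmetric equilibrium size under sharing.

    Returns (dp*_2, r_eq_2): the two-bleb shared-patch nucleation
    pressure and the symmetric stable equilibrium radius at ``delta_p``
    (None if none exists there). Sharing halves each bleb's reservoir,
    so dp*_2 exceeds the single-bleb dp* and r_eq_2 is smaller than the
    single-bleb stable radius.
    """
    dp_star_2 = delta_p_star(params, n_blebs=2)
    stable = [e for e in equilibria(delta_p, params, n_blebs=2) if e.stable]
    r_eq_2 = stable[-1].r_eq if stable else None
    return dp_star_2, r_eq_2
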