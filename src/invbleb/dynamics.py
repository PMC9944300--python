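"""Time integration of the coupled inverse-bleb / cell system.

The dynamical variables are each bleb's radius r_i and its relaxing
cortical tension. The radius follows the overdamped Rayleigh-Plesset
balance

    dr/dt = r/(4 mu) * (dp - P - 2 Sigma / r),

where dp is the applied (gauge) pressure drop and the intracellular
pressure P = 2 sigma / R is slaved instantaneously to the cell's Laplace
equilibrium. The cell radius R follows from exact volume conservation,
the opening angle from the pore constraint, and the tensions from the
two-regime law in :mod:`invbleb.tension`. The system is stiff once a
bleb enters the membrane-dominated regime (the tension then rises
exponentially in area), so integration uses an implicit Radau scheme
with event detection for collapse (r = a) and regime switches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import geometry, tension
from .params import ModelParams, Protocol, pressure_to_mmhg

__all__ = [
    "PatchAssignment",
    "SystemState",
    "TrajectoryEvent",
    "Trajectory",
    "radius_rhs",
    "simulate",
    "collapse_run",
    "time_to_steady",
    "NOT_REACHED",
]

#: Sentinel returned by time_to_steady when the target is never reached.
NOT_REACHED = float("nan")

RTOL = 1e-8
ATOL = 1e-10


@dataclass(frozen=True)
class PatchAssignment:
    """Partition of bleb indices into tension-equilibration patches.

    Blebs nucleated closer than the patch radius d share one patch (one
    stretched area S, hence one target tension); farther apart they are
    independent. Positions are not modelled: only the partition matters.
    """

    groups: tuple[tuple[int, ...], ...]

    @classmethod
    def independent(cls, n: int) -> "PatchAssignment":
        return cls(tuple((i,) for i in range(n)))

    @classmethod
    def shared(cls, n: int) -> "PatchAssignment":
        return cls((tuple(range(n)),))

    @property
    def n_blebs(self) -> int:
        return sum(len(g) for g in self.groups)

    @property
    def n_patches(self) -> int:
        return len(self.groups)

    def validate(self, params: ModelParams) -> "PatchAssignment":
        seen: set[int] = set()
        for g in self.groups:
            for i in g:
                if i in seen:
                    raise ValueError(f"bleb {i} assigned to more than one patch")
                seen.add(i)
            if len(g) * params.a**2 >= params.d**2:
                raise ValueError(
                    f"patch cannot host {len(g)} pores: n*a^2 >= d^2"
                )
        if seen != set(range(len(seen))):
            raise ValueError("bleb indices must be 0..n-1")
        return self


@dataclass(frozen=True)
class SystemState:
    """Instantaneous state of the cell and all blebs (arrays over blebs)."""

    t: float
    r: np.ndarray
    theta: np.ndarray
    Sigma: np.ndarray
    regime: tuple[str, ...]
    R: float
    sigma: float
    P: float
    eps_B: np.ndarray
    eps_C: float
    alive: np.ndarray


@dataclass(frozen=True)
class TrajectoryEvent:
    t: float
    kind: str  # collapsed | steady | regime_switch | lytic
    bleb: int | None = None


@dataclass
class Trajectory:
    """Time-ordered system states with event annotations.

    ``r``, ``Sigma`` etc. are (n_times, n_blebs) arrays; collapsed blebs
    are pinned at r = a from their collapse time on. ``interpolate``
    gives dense access to the radii via the integrator's own
    interpolants.
    """

    t: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    Sigma: np.ndarray
    R: np.ndarray
    sigma: np.ndarray
    P: np.ndarray
    eps_B: np.ndarray
    eps_C: np.ndarray
    regime: np.ndarray
    events: list[TrajectoryEvent]
    params: ModelParams
    protocol: Protocol
    assignment: PatchAssignment
    _segments: list = field(default_factory=list, repr=False)

    @property
    def n_blebs(self) -> int:
        return self.r.shape[1]

    @property
    def terminal_event(self) -> TrajectoryEvent | None:
        """The event that ended integration before t_max, if any."""
        if self.t[-1] >= self.protocol.t_max - 1e-9:
            return None
        for ev in reversed(self.events):
            if ev.kind in ("collapsed", "lytic"):
                return ev
        return None

    def collapse_times(self) -> dict[int, float]:
        return {ev.bleb: ev.t for ev in self.events if ev.kind == "collapsed"}

    def final_radii(self) -> np.ndarray:
        return self.r[-1].copy()

    def interpolate(self, times) -> np.ndarray:
        """Radii at arbitrary times within the integrated window,
        evaluated from the stored dense-output interpolants."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.empty((times.size, self.n_blebs))
        for k, tq in enumerate(times):
            for (t0, t1, sol, idx, frozen_r) in self._segments:
                if t0 - 1e-12 <= tq <= t1 + 1e-12:
                    y = sol(np.clip(tq, t0, t1))
                    row = frozen_r.copy()
                    row[idx] = y[: len(idx)]
                    out[k] = row
                    break
            else:
                raise ValueError(f"time {tq} outside trajectory window")
        return out

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"t_s": self.t}
        for i in range(self.n_blebs):
            suf = "" if self.n_blebs == 1 else f"_{i + 1}"
            cols[f"r_um{suf}"] = self.r[:, i]
            cols[f"theta_rad{suf}"] = self.theta[:, i]
            cols[f"Sigma_pN_per_um{suf}"] = self.Sigma[:, i]
            cols[f"eps_B{suf}"] = self.eps_B[:, i]
            cols[f"regime{suf}"] = self.regime[:, i]
        cols["R_um"] = self.R
        cols["sigma_pN_per_um"] = self.sigma
        cols["P_pN_per_um2"] = self.P
        cols["eps_C"] = self.eps_C
        return pd.DataFrame(cols)


def radius_rhs(r: float, Sigma: float, P: float, delta_p: float,
               params: ModelParams) -> float:
    """Overdamped Rayleigh-Plesset rate dr/dt = r/(4 mu)(dp - P - 2 Sigma/r)."""
    return r / (4.0 * params.mu) * (delta_p - P - 2.0 * Sigma / r)


class _Model:
    """RHS and observables for a fixed set of active blebs."""

    def __init__(self, params: ModelParams, assignment: PatchAssignment,
                 active: np.ndarray, delta_p: float, frozen_cell: bool):
        self.p = params
        self.assignment = assignment
        self.active = active  # bool mask over all blebs
        self.delta_p = delta_p
        self.frozen_cell = frozen_cell
        self.idx = np.flatnonzero(active)
        self.n_act = len(self.idx)
        self.S0 = np.pi * params.d**2
        self.n_patches = assignment.n_patches
        self.A0 = geometry.cell_area(params.R0, params.d, self.n_patches)

    def observables(self, y: np.ndarray):
        p = self.p
        r_act = y[: self.n_act]
        Sig_relax = y[self.n_act:]
        r_act = np.maximum(r_act, p.a)
        theta_act = geometry.opening_angle(r_act, p.a)
        if self.frozen_cell:
            R = p.R0
            sigma = p.sigma_0
        else:
            R = geometry.cell_radius(r_act, p.a, p.R0)
            A = geometry.cell_area(R, p.d, self.n_patches)
            sigma = tension.effective_tension(p.sigma_0, A, self.A0, p)
        P = 2.0 * sigma / R
        # per-patch stretched area; collapsed blebs keep their pore
        # footprint but contribute no cap
        S_patch = {}
        for g in self.assignment.groups:
            live = [i for i in g if self.active[i]]
            radii = [r_act[np.searchsorted(self.idx, i)] for i in live]
            S_patch[g] = geometry.patch_area(radii, p.d, p.a, n_pores=len(g))
        Sigma_eff = np.empty(self.n_act)
        eps_B = np.empty(self.n_act)
        for k, i in enumerate(self.idx):
            g = next(g for g in self.assignment.groups if i in g)
            S = S_patch[g]
            Sigma_eff[k] = tension.effective_tension(Sig_relax[k], S, self.S0, p)
            eps_B[k] = (S - self.S0) / self.S0
        return r_act, theta_act, Sigma_eff, Sig_relax, R, sigma, P, eps_B

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.p
        r_act, _, Sigma_eff, Sig_relax, _, _, P, _ = self.observables(y)
        drdt = r_act / (4.0 * p.mu) * (self.delta_p - P - 2.0 * Sigma_eff / r_act)
        dSdt = (p.sigma_0 - Sig_relax) / p.tau_c
        return np.concatenate([drdt, dSdt])


def _integrate(params: ModelParams, protocol: Protocol,
               inits: Sequence[tuple[float, float]],
               assignment: PatchAssignment,
               frozen_cell: bool = False,
               n_samples: int = 800) -> Trajectory:
    """Integrate N blebs with collapse freezing; shared core of
    :func:`simulate` and :func:`invbleb.multibleb.simulate_multi`."""
    assignment.validate(params)
    n = assignment.n_blebs
    if len(inits) != n:
        raise ValueError("one (r0, Sigma0) pair required per bleb")
    for r0, Sigma0 in inits:
        if r0 < params.a:
            raise ValueError(f"initial radius {r0} below pore half-width {params.a}")
        if Sigma0 < 0:
            raise ValueError("initial tension must be >= 0")
    delta_p = protocol.applied_delta_p

    active = np.ones(n, dtype=bool)
    r_cur = np.array([float(x[0]) for x in inits])
    Sig_cur = np.array([float(x[1]) for x in inits])
    events: list[TrajectoryEvent] = []
    segments: list = []
    chunks: list[tuple[np.ndarray, _Model, np.ndarray]] = []
    t0 = 0.0
    lytic = False

    while t0 < protocol.t_max and active.any():
        # blebs already at the pore radius and still shrinking collapse
        # immediately: the model is only valid down to r = a, and an
        # event rooted exactly at the initial time would be degenerate
        swept = True
        while swept and active.any():
            swept = False
            model = _Model(params, assignment, active.copy(), delta_p,
                           frozen_cell)
            y0 = np.concatenate([r_cur[active], Sig_cur[active]])
            dy0 = model.rhs(t0, y0)
            for k in range(model.n_act):
                if (y0[k] <= params.a * (1.0 + 1e-12)) and dy0[k] <= 0.0:
                    i = int(model.idx[k])
                    events.append(TrajectoryEvent(t=t0, kind="collapsed", bleb=i))
                    active[i] = False
                    r_cur[i] = params.a
                    swept = True
                    break
        if not active.any():
            break
        model = _Model(params, assignment, active.copy(), delta_p, frozen_cell)
        y0 = np.concatenate([r_cur[active], Sig_cur[active]])

        ev_funcs: list[Callable] = []
        for k in range(model.n_act):
            def make_collapse(k=k):
                def g(t, y, model=model):
                    return y[k] - params.a
                g.terminal = True
                g.direction = -1.0
                return g
            ev_funcs.append(make_collapse())
        eps_star = params.eps_star
        for k in range(model.n_act):
            def make_regime(k=k):
                def g(t, y, model=model):
                    return model.observables(y)[7][k] - eps_star
                g.terminal = False
                g.direction = 0.0
                return g
            ev_funcs.append(make_regime())

        try:
            sol = solve_ivp(model.rhs, (t0, protocol.t_max), y0, method="Radau",
                            rtol=RTOL, atol=ATOL, dense_output=True,
                            events=ev_funcs)
        except tension.LyticOverflowError:
            events.append(TrajectoryEvent(t=t0, kind="lytic"))
            lytic = True
            break
        if not sol.success:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"integrator failed at t={sol.t[-1]:.6g}s: {sol.message}; "
                f"state={sol.y[:, -1]}"
            )

        t1 = float(sol.t[-1])
        ts = np.linspace(t0, t1, max(2, int(np.ceil((t1 - t0) /
                         (protocol.t_max / n_samples))) + 1))
        ys = sol.sol(ts)
        segments.append((t0, t1, sol.sol, model.idx.copy(), r_cur.copy()))
        chunks.append((ts, model, ys))

        collapsed_now = [k for k in range(model.n_act) if len(sol.t_events[k])]
        for k in range(model.n_act, 2 * model.n_act):
            for te in sol.t_events[k]:
                events.append(TrajectoryEvent(t=float(te), kind="regime_switch",
                                              bleb=int(model.idx[k - model.n_act])))
        y_end = sol.y[:, -1]
        r_cur[active] = np.maximum(y_end[: model.n_act], params.a)
        Sig_cur[active] = y_end[model.n_act:]
        if collapsed_now:
            for k in collapsed_now:
                i = int(model.idx[k])
                events.append(TrajectoryEvent(t=t1, kind="collapsed", bleb=i))
                active[i] = False
                r_cur[i] = params.a
            t0 = t1
            continue
        break  # reached t_max without terminal event

    if not chunks:
        # every bleb collapsed at t = 0: synthesize a single sample
        model = _Model(params, assignment, np.zeros(n, dtype=bool), delta_p,
                       frozen_cell)
        chunks.append((np.array([t0]), model, np.empty((0, 1))))

    # assemble sampled arrays (dropping duplicated segment boundaries)
    all_t, rows = [], []
    for ts, model, ys in chunks:
        for j, tq in enumerate(ts):
            if all_t and tq <= all_t[-1] + 1e-15:
                all_t.pop()
                rows.pop()
            y = ys[:, j]
            r_act, th_act, Sig_eff, _, R, sigma, P, eps_B_act = model.observables(y)
            r_full = np.full(n, params.a)
            th_full = np.full(n, np.pi / 2.0)
            Sig_full = np.full(n, params.sigma_0)
            eps_full = np.zeros(n)
            reg_full = np.array([tension.CORTEX] * n, dtype=object)
            r_full[model.idx] = r_act
            th_full[model.idx] = th_act
            Sig_full[model.idx] = Sig_eff
            eps_full[model.idx] = eps_B_act
            reg_full[model.idx] = [
                tension.regime(e, params) for e in eps_B_act
            ]
            A = geometry.cell_area(R, params.d, model.n_patches)
            eps_C = (A - model.A0) / model.A0
            all_t.append(tq)
            rows.append((r_full, th_full, Sig_full, R, sigma, P, eps_full,
                         eps_C, reg_full))

    t_arr = np.array(all_t)
    traj = Trajectory(
        t=t_arr,
        r=np.array([x[0] for x in rows]),
        theta=np.array([x[1] for x in rows]),
        Sigma=np.array([x[2] for x in rows]),
        R=np.array([x[3] for x in rows]),
        sigma=np.array([x[4] for x in rows]),
        P=np.array([x[5] for x in rows]),
        eps_B=np.array([x[6] for x in rows]),
        eps_C=np.array([x[7] for x in rows]),
        regime=np.array([x[8] for x in rows], dtype=object),
        events=sorted(events, key=lambda e: e.t),
        params=params,
        protocol=protocol,
        assignment=assignment,
        _segments=segments,
    )
    if lytic and not traj.t.size:
        raise tension.LyticOverflowError("lytic overflow at the initial state")
    return traj


def simulate(params: ModelParams, protocol: Protocol,
             init: tuple[float, float] | None = None,
             _frozen_cell: bool = False) -> Trajectory:
    """Integrate a single inverse bleb under a perfusion protocol.

    ``init`` is the nucleation condition (r0, Sigma0); the default is a
    hemispherical nucleus pinned to the pore with a locally disrupted
    cortex, r0 = a and Sigma0 = sigma_m. Integration stops at t_max or
    at collapse (the model is valid only down to r = a).

    ``_frozen_cell`` pins the cell at (R0, sigma_0), turning the cortex
    regime into a linear ODE with a closed-form solution; it exists as a
    diagnostic/benchmark mode and is not part of the physical model.
    """
    if init is None:
        init = (params.a, params.sigma_m)
    return _integrate(params, protocol, [init], PatchAssignment.independent(1),
                      frozen_cell=_frozen_cell)


def collapse_run(params: ModelParams, delta_p_prepare: float,
                 t_max: float = 1800.0) -> Trajectory:
    """Deflation after pressure removal, from the steady state.

    The vacuole is prepared at the stable (membrane-branch) equilibrium
    for ``delta_p_prepare``; at t = 0+ the pressure drop is set to zero
    and the system integrated until r returns to the pore radius a.
    """
    from .steady import equilibria  # deferred: steady imports geometry/tension only

    stable = [e for e in equilibria(delta_p_prepare, params) if e.stable]
    if not stable:
        raise ValueError(
            f"no stable equilibrium at delta_p={delta_p_prepare} pN/um^2 "
            f"({pressure_to_mmhg(delta_p_prepare):.3g} mmHg)"
        )
    eq = stable[-1]
    protocol = Protocol(delta_p=delta_p_prepare, t_max=t_max,
                        schedule="step_to_zero")
    return _integrate(params, protocol, [(eq.r_eq, eq.Sigma_eq)],
                      PatchAssignment.independent(1))


def collapse_time(traj: Trajectory, minutes: bool = True) -> float:
    """First-passage time to r = a, from the trajectory's collapse event."""
    for ev in traj.events:
        if ev.kind == "collapsed":
            return ev.t / 60.0 if minutes else ev.t
    return NOT_REACHED


def time_to_steady(traj: Trajectory, r_star: float, rtol: float = 0.01,
                   bleb: int = 0) -> float:
    """First time (minutes) with |r - r_star| <= rtol * r_star.

    Returns NaN (``NOT_REACHED``) if the band is never entered. The
    crossing is located on the sampled grid and refined by bisection on
    the dense interpolant.
    """
    band = rtol * abs(r_star)
    dev = np.abs(traj.r[:, bleb] - r_star) - band
    inside = dev <= 0
    if not inside.any():
        return NOT_REACHED
    j = int(np.argmax(inside))
    if j == 0:
        return 0.0
    lo, hi = traj.t[j - 1], traj.t[j]
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if abs(traj.interpolate(mid)[0, bleb] - r_star) - band <= 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-9 * max(1.0, hi):
            break
    return hi / 60.0
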