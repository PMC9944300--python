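"""Spherical-cap geometry of the inverse bleb and exact volume conservation.

The bleb is a spherical cap of radius r and opening angle theta in
[pi/2, pi], pinned to a basal pore of half-width a by r*sin(theta) = a
(the branch with theta >= pi/2). The cell stays hemispherical with
radius R fixed by conservation of the cytosolic volume: the hemisphere
volume grows by exactly the summed cap volumes, equivalently
R^3 = R0^3 + sum_i 2 r_i^3 (2 + cos theta_i) sin^4(theta_i / 2).
The basal pore's own volumetric contribution is neglected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import ModelParams

__all__ = [
    "BlebGeometry",
    "opening_angle",
    "cap_volume",
    "cap_area",
    "cell_radius",
    "patch_area",
    "cell_area",
    "strains",
]


def opening_angle(r, a):
    """Opening angle theta = pi - arcsin(a/r) of a cap pinned to the pore.

    Vectorised over ``r``. Raises ``ValueError`` if any r < a (the bleb
    cannot be smaller than the pore mouth).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < a):
        raise ValueError(f"bleb radius r={r} smaller than pore half-width a={a}")
    theta = np.pi - np.arcsin(np.clip(a / r, -1.0, 1.0))
    return theta if theta.ndim else float(theta)


def cap_volume(r, theta):
    """Volume (4*pi/3) r^3 (2 + cos theta) sin^4(theta/2) of a spherical cap."""
    r = np.asarray(r, dtype=float)
    v = (4.0 * np.pi / 3.0) * r**3 * (2.0 + np.cos(theta)) * np.sin(theta / 2.0) ** 4
    return v if v.ndim else float(v)


def cap_area(r, theta):
    """Curved surface area 2*pi*r^2 (1 - cos theta) of a spherical cap."""
    r = np.asarray(r, dtype=float)
    s = 2.0 * np.pi * r**2 * (1.0 - np.cos(theta))
    return s if s.ndim else float(s)


@dataclass(frozen=True)
class BlebGeometry:
    """Instantaneous geometry of one inverse bleb."""

    r: float
    theta: float
    cap_volume: float
    cap_area: float

    @classmethod
    def from_radius(cls, r: float, a: float) -> "BlebGeometry":
        theta = opening_angle(r, a)
        return cls(r=float(r), theta=float(theta),
                   cap_volume=cap_volume(r, theta), cap_area=cap_area(r, theta))


def cell_radius(radii: Sequence[float], a: float, R0: float) -> float:
    """Cell radius from exact volume conservation.

    The hemispherical cell absorbs the summed cap volumes of all blebs:
    (2*pi/3) R^3 = (2*pi/3) R0^3 + sum_i V_cap(r_i, theta_i).
    """
    extra = 0.0
    for r in radii:
        theta = opening_angle(r, a)
        extra += cap_volume(r, theta)
    if extra == 0.0:
        return float(R0)
    return float(np.cbrt(R0**3 + extra * 3.0 / (2.0 * np.pi)))


def patch_area(radii: Sequence[float], d: float, a: float,
               n_pores: int | None = None) -> float:
    """Stretched area S of one tension-equilibration patch hosting n blebs.

    S = sum_i 2*pi*r_i^2 (1 - cos theta_i) + pi (d^2 - n a^2): the flat
    annulus of the patch minus the n pore footprints, plus each bleb's
    curved cap. Reduces to the single-bleb form for n = 1. ``n_pores``
    overrides the footprint count when a collapsed bleb's cap is gone
    but its pore remains.
    """
    n = len(radii) if n_pores is None else n_pores
    if np.pi * d**2 <= n * np.pi * a**2:
        raise ValueError(
            f"patch of radius d={d} cannot host {n} pore footprints of half-width a={a}"
        )
    s = np.pi * (d**2 - n * a**2)
    for r in radii:
        s += cap_area(r, opening_angle(r, a))
    return float(s)


def cell_area(R: float, d: float, n_patches: int = 1) -> float:
    """Cell area entering the cell strain: 3*pi*R^2 - n_patches*pi*d^2."""
    return float(3.0 * np.pi * R**2 - n_patches * np.pi * d**2)


def strains(S: float, A: float, params: ModelParams, n_patches: int = 1):
    """Relative area strains (eps_B, eps_C) of the bleb patch and the cell.

    eps_B = (S - S0)/S0 with S0 = pi d^2 (resting patch area);
    eps_C = (A - A0)/A0 with A0 = 3*pi*R0^2 - n_patches*pi*d^2.
    """
    S0 = np.pi * params.d**2
    A0 = cell_area(params.R0, params.d, n_patches)
    return float((S - S0) / S0), float((A - A0) / A0)
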