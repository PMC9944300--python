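"""Writers: trajectory and scan tables as CSV, run manifests as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .dynamics import Trajectory
from .steady import EquilibriumRecord

__all__ = ["write_trajectory", "write_records", "write_manifest"]


def write_trajectory(traj: Trajectory, path) -> Path:
    """Trajectory table with a one-line comment header carrying the
    protocol and parameter provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = json.dumps({
        "params": traj.params.to_dict(),
        "protocol": {"delta_p": traj.protocol.delta_p,
                     "t_max": traj.protocol.t_max,
                     "schedule": traj.protocol.schedule},
        "events": [{"t_s": ev.t, "kind": ev.kind, "bleb": ev.bleb}
                   for ev in traj.events],
        "version": __version__,
    })
    with path.open("w") as fh:
        fh.write(f"# {header}\n")
        traj.to_dataframe().to_csv(fh, index=False)
    return path


def write_records(records: list[EquilibriumRecord], path) -> Path:
    """Equilibrium records as a CSV table sorted by pressure then radius."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([{
        "delta_p_mmHg": e.delta_p_mmhg,
        "delta_p_pN_per_um2": e.delta_p,
        "r_um": e.r_eq,
        "R_um": e.R_eq,
        "Sigma_pN_per_um": e.Sigma_eq,
        "sigma_pN_per_um": e.sigma_eq,
        "branch": e.branch,
        "stable": e.stable,
        "volume_um3": e.vacuole_volume,
    } for e in records])
    if len(df):
        df = df.sort_values(["delta_p_mmHg", "r_um"])
    df.to_csv(path, index=False)
    return path


def write_manifest(cfg: RunConfig, path, extra: dict | None = None) -> Path:
    """JSON manifest sufficient to reproduce the run bit-for-bit; loads
    back through :func:`invbleb.config.config_from_dict`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = cfg.to_dict()
    doc["params"].pop("sigma_0", None)  # derived; config schema rejects it
    if extra:
        doc = {**doc, "_run": extra}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path
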