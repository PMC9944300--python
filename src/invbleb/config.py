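"""JSON run configuration: strict schema, mmHg conversion at the boundary.

A config is a JSON object with up to four sections::

    {
      "params":   {"R0": 10, "d": 10, "eps_star": 0.5, ...},
      "protocol": {"delta_p_mmHg": 30, "t_max_min": 10, "schedule": "constant"},
      "init":     {"r0": 0.25, "Sigma0": 40},
      "seed":     0
    }

Every key is optional and defaults to the reference parameter set and
the nucleation initial condition. Pressures may be given in internal
units (``delta_p``) or in mmHg with the ``_mmHg`` suffix; unknown keys
anywhere are an error, never silently ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

from .params import (ModelParams, Protocol, mmhg_to_pressure,
                     reference_params, validate)

__all__ = ["RunConfig", "ConfigError", "load_config", "config_from_dict"]


class ConfigError(ValueError):
    """Malformed run configuration."""


@dataclass(frozen=True)
class RunConfig:
    params: ModelParams
    protocol: Protocol
    r0: float
    Sigma0: float
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "protocol": {
                "delta_p": self.protocol.delta_p,
                "t_max": self.protocol.t_max,
                "schedule": self.protocol.schedule,
            },
            "init": {"r0": self.r0, "Sigma0": self.Sigma0},
            "seed": self.seed,
        }


_PARAM_KEYS = {f.name for f in fields(ModelParams)} - {"sigma_0"}
_PROTOCOL_KEYS = {"delta_p", "delta_p_mmHg", "t_max", "t_max_min", "schedule"}
_INIT_KEYS = {"r0", "Sigma0"}
#: "_run" carries manifest metadata (events, versions); ignored on load
#: so manifests round-trip through load_config.
_TOP_KEYS = {"params", "protocol", "init", "seed", "_run"}


def _reject_unknown(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; "
            f"allowed: {sorted(allowed)}"
        )


def config_from_dict(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a JSON object")
    _reject_unknown(doc, _TOP_KEYS, "config root")

    psec = doc.get("params", {})
    _reject_unknown(psec, _PARAM_KEYS, "'params'")
    params = validate(reference_params().replace(**psec))

    proto = dict(doc.get("protocol", {}))
    _reject_unknown(proto, _PROTOCOL_KEYS, "'protocol'")
    if "delta_p" in proto and "delta_p_mmHg" in proto:
        raise ConfigError("give delta_p or delta_p_mmHg, not both")
    if "t_max" in proto and "t_max_min" in proto:
        raise ConfigError("give t_max or t_max_min, not both")
    delta_p = (mmhg_to_pressure(proto["delta_p_mmHg"])
               if "delta_p_mmHg" in proto else proto.get("delta_p", 0.0))
    t_max = (proto["t_max_min"] * 60.0
             if "t_max_min" in proto else proto.get("t_max", 600.0))
    protocol = Protocol(delta_p=float(delta_p), t_max=float(t_max),
                        schedule=proto.get("schedule", "constant"))

    init = dict(doc.get("init", {}))
    _reject_unknown(init, _INIT_KEYS, "'init'")
    r0 = float(init.get("r0", params.a))
    Sigma0 = float(init.get("Sigma0", params.sigma_m))

    seed = int(doc.get("seed", 0))
    return RunConfig(params=params, protocol=protocol, r0=r0, Sigma0=Sigma0,
                     seed=seed)


def load_config(path) -> RunConfig:
    """Parse and validate a JSON run configuration file."""
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"invalid JSON in {path}: {exc}") from exc
    return config_from_dict(doc)
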