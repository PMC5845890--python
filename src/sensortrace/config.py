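"""Run configuration: sensor presets, compartment pH, thresholds, seeds.

All defaults are overridable from a YAML file; the effective configuration
is echoed into every result record so reruns are auditable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import yaml

from .sensors import ATEAM103, RCAMP1E, ROGFP1, E0_DTT_HANSON, PhysConstants, SensorSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    # sensor presets
    calcium_sensor: SensorSpec = RCAMP1E
    atp_sensor: SensorSpec = ATEAM103
    redox_sensor: SensorSpec = ROGFP1
    e0_dtt: float = E0_DTT_HANSON
    # compartment pH
    ph_cytosol: float = 7.0
    ph_mitochondria: float = 7.98
    # detection thresholds and windows
    responder_k: float = 3.0
    event_k: float = 3.0
    refractory_s: float = 1.0
    sync_window_s: float = 1.0
    min_participation: float = 0.2
    rate_auto_length_s: float = 20.0
    plateau_fraction: float = 0.2
    # randomness
    seed: int = 0

    @property
    def constants(self) -> PhysConstants:
        return PhysConstants(e0_dtt=self.e0_dtt)

    def effective(self) -> dict:
        d = asdict(self)
        d["calcium_sensor"] = asdict(self.calcium_sensor)
        d["atp_sensor"] = asdict(self.atp_sensor)
        d["redox_sensor"] = asdict(self.redox_sensor)
        return d


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Sensor entries in YAML are mappings of SensorSpec fields, e.g.
    ``atp_sensor: {name: ATeam1.03, kd: 3.3, hill_coefficient: 2.1,
    dynamic_range: 2.3}``.
    """
    data = {}
    if path:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    for key in ("calcium_sensor", "atp_sensor", "redox_sensor"):
        if key in data and isinstance(data[key], dict):
            data[key] = SensorSpec(**data[key])
    return RunConfig(**data)
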