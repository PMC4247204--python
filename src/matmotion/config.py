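"""Session/pipeline configuration with a documented JSON schema.

A single flat JSON object configures the whole pipeline; every key is
optional and defaults to the values below.  Schema (units in brackets)::

    {
      "placement": "two_imus" | "upper_only" | "forearm_only",
      "l_ua": 0.07,              # upper-arm length [m]
      "l_fa": 0.07,              # forearm length [m]
      "pixel_threshold": 2.0,    # noise floor [device units]
      "min_area": 3,             # artefact filter [pixels]
      "min_load": 10.0,          # artefact filter [device units]
      "trunk_radius": 0.12,      # trunk-imprint gathering radius [m]
      "trust_load_ref": 500.0,   # trust ramp saturation [device units]
      "trust_length_ref": 0.10,  # trust ramp saturation [m]
      "trust_dist_ref": 0.30,    # trust zero distance [m]
      "shoulder_half_separation": 0.06,   # [m]
      "shoulder_cranial_offset": 0.10,    # [m]
      "shoulder_height": 0.05,            # [m]
      "v_on": 0.05, "v_off": 0.02,        # movement hysteresis [m/s]
      "d_min": 0.3,                       # minimum movement duration [s]
      "sal_wc": 10.0,                     # SAL band [Hz]
      "lowpass_fc": 6.0,                  # velocity filter cutoff [Hz]
      "ukf": { ... per-unit overrides of UkfParams fields ... }
    }
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

from .imu_fusion import UkfParams
from .kinematics import Placement


@dataclass
class Config:
    placement: str = Placement.TWO_IMUS.value
    l_ua: float = 0.07
    l_fa: float = 0.07
    pixel_threshold: float = 2.0
    min_area: int = 3
    min_load: float = 10.0
    trunk_radius: float = 0.12
    trust_load_ref: float = 500.0
    trust_length_ref: float = 0.10
    trust_dist_ref: float = 0.30
    shoulder_half_separation: float = 0.06
    shoulder_cranial_offset: float = 0.10
    shoulder_height: float = 0.05
    v_on: float = 0.05
    v_off: float = 0.02
    d_min: float = 0.3
    sal_wc: float = 10.0
    lowpass_fc: float = 6.0
    ukf: dict[str, Any] = field(default_factory=dict)

    def ukf_params(self, unit: str = "") -> UkfParams:
        """UkfParams with global then per-unit overrides applied."""
        kwargs = {k: v for k, v in self.ukf.items() if not isinstance(v, dict)}
        kwargs.update(self.ukf.get(unit, {}) if isinstance(self.ukf.get(unit), dict) else {})
        return UkfParams(**kwargs)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "Config":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
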