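"""Framework configuration: every constant of the method in one place.

Defaults reproduce the published framework exactly — 150 m land-cover
buffer, 4-connected edge detection, six one-foot inundation scenarios,
1.2 m connectedness scenario, hardened-shoreline weight 1.5, migration
weight 2.0, and the 6 / -6 ordinal thresholds.  Any override is logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field

import yaml

from .adaptive import FOOT
from .scoring import MetricDirections, _DEFAULT_SIGNS, _DEFAULT_WEIGHTS

logger = logging.getLogger("marshres")

__all__ = ["FrameworkConfig"]


@dataclass
class FrameworkConfig:
    buffer_m: float = 150.0
    connectivity: int = 4
    scenarios_m: tuple[float, ...] = tuple(i * FOOT for i in range(1, 7))
    connectedness_slr_m: float = 1.2
    connected_inundation: bool = True
    ordinal_threshold: float = 6.0
    signs: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_SIGNS))
    weights: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    sd_ddof: int = 1
    seed: int = 0

    def directions(self) -> MetricDirections:
        return MetricDirections(signs=dict(self.signs), weights=dict(self.weights))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios_m"] = list(self.scenarios_m)
        return d

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "FrameworkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        defaults = cls()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                value = raw[f.name]
                if f.name == "scenarios_m":
                    value = tuple(float(v) for v in value)
                default = getattr(defaults, f.name)
                if value != default:
                    logger.info("config override: %s = %r (default %r)", f.name, value, default)
                kwargs[f.name] = value
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
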