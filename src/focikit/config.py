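"""Run configuration: every knob of a pipeline run in one serializable object.

A serialized :class:`RunConfig` (YAML or JSON) plus its seed fully
determines a run; the SHA-256 hash of its canonical JSON form is stamped on
every output table so results can be traced back to the exact parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detect import DetectionParams
from .simulate import (CaptureParams, KineticsParams, NoiseModel, OpticsModel,
                       SimLayout)


@dataclass
class RunConfig:
    seed: int = 0
    layout: SimLayout = field(default_factory=SimLayout)
    optics: OpticsModel = field(default_factory=OpticsModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    capture: CaptureParams = field(default_factory=CaptureParams)
    drift_px: float = 0.0
    max_displacement_px: float | None = None  # None -> median nucleus radius
    histogram_bandwidth: float = 1.0
    fast_threshold: float = 0.85
    input_paths: list[str] = field(default_factory=list)
    output_dir: str = "focikit_out"

    _BLOCKS = {"layout": SimLayout, "optics": OpticsModel, "noise": NoiseModel,
               "kinetics": KineticsParams, "detection": DetectionParams,
               "capture": CaptureParams}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kinetics"]["timepoints_min"] = list(d["kinetics"]["timepoints_min"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for name, typ in cls._BLOCKS.items():
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = typ(**kwargs[name])
        return cls(**kwargs)

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text))
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
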