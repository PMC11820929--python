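"""YAML run configuration shared by the CLI commands.

Keys mirror the module they configure::

    io:        {fps: 25}
    light:     {threshold: 40, hysteresis: 10}
    detection: {confidence_threshold: 0.25, area_split_px: 1100, ...}
    flow:      {window: 21, pyramid_levels: 3, max_features: 50, ...}
    activity:  {walk_threshold_px_per_s: 5.0, window_s: 1.0}

Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .activity import ThresholdConfig
from .detection import DetectorParams
from .flow import FlowParams

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    fps: int = 25
    light_threshold: float = 40.0
    light_hysteresis: float = 10.0
    detection: DetectorParams = field(default_factory=DetectorParams)
    detection_confidence_threshold: float = 0.25
    flow: FlowParams = field(default_factory=FlowParams)
    activity: ThresholdConfig = field(default_factory=ThresholdConfig)


def _build(cls: type, section: dict[str, Any], name: str) -> Any:
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")
    return cls(**section)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"io", "light", "detection", "flow", "activity"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    io = dict(raw.get("io", {}))
    light = dict(raw.get("light", {}))
    det = dict(raw.get("detection", {}))
    conf_thr = det.pop("confidence_threshold", 0.25)
    act = dict(raw.get("activity", {}))
    if "window_s" in act:
        act["accumulation_window_s"] = act.pop("window_s")
    return RunConfig(
        fps=int(io.get("fps", 25)),
        light_threshold=float(light.get("threshold", 40.0)),
        light_hysteresis=float(light.get("hysteresis", 10.0)),
        detection=_build(DetectorParams, det, "detection"),
        detection_confidence_threshold=float(conf_thr),
        flow=_build(FlowParams, dict(raw.get("flow", {})), "flow"),
        activity=_build(ThresholdConfig, act, "activity"),
    )
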