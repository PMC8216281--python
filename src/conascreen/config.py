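"""Run configuration: channel roles and per-stage parameters.

A run needs exactly one reference channel (the RNA/bait channel used for
bead detection and as the ratio denominator) and one signal channel (the
protein channel whose attenuation reports inhibition).  Defaults name
them FITC and mCherry after the common filter sets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detect import DetectParams
from .errors import ConfigError
from .ringquant import QuantParams


@dataclass(frozen=True)
class ScreenParams:
    min_beads: int = 50
    rule_a_k: float = 3.0
    rule_b_k: float = 6.0

    def __post_init__(self) -> None:
        if self.min_beads < 1:
            raise ConfigError("min_beads must be >= 1")
        if self.rule_a_k <= 0 or self.rule_b_k <= 0:
            raise ConfigError("hit-rule multipliers must be > 0")


@dataclass(frozen=True)
class RunConfig:
    reference_channel: str = "FITC"
    signal_channel: str = "mCherry"
    detect: DetectParams = field(default_factory=DetectParams)
    quant: QuantParams = field(default_factory=QuantParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    min_doses_for_fit: int = 5
    seed: int = 0
    output_dir: str = "conascreen-out"

    def __post_init__(self) -> None:
        if self.reference_channel == self.signal_channel:
            raise ConfigError(
                "reference and signal channels must be distinct"
            )

    @property
    def channels(self) -> tuple[str, str]:
        return (self.reference_channel, self.signal_channel)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples -> lists for clean YAML/JSON round-trips
        d["detect"]["expected_radius_range_px"] = list(
            self.detect.expected_radius_range_px
        )
        d["quant"]["angles_deg"] = list(self.quant.angles_deg)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "detect" in data:
            det = dict(data["detect"])
            if "expected_radius_range_px" in det:
                det["expected_radius_range_px"] = tuple(
                    det["expected_radius_range_px"]
                )
            data["detect"] = DetectParams(**det)
        if "quant" in data:
            q = dict(data["quant"])
            if "angles_deg" in q:
                q["angles_deg"] = tuple(q["angles_deg"])
            data["quant"] = QuantParams(**q)
        if "screen" in data:
            data["screen"] = ScreenParams(**dict(data["screen"]))
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix.lower() == ".json"
        else yaml.safe_load(text)
    )
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not hold a mapping")
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig) -> str:
    """Render every numeric default as YAML."""
    return yaml.safe_dump(config.to_dict(), sort_keys=False)
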