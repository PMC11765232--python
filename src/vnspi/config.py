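"""Run configuration: one hierarchical YAML file, strict keys, lossless round trip.

CLI flags override config values; the precedence is flag > file > default.
Every written artifact carries the configuration hash and seed so any result
is regenerable from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or unknown configuration content, with the offending key path."""


@dataclass
class PatternsSection:
    image_side: int = 32
    ordering: str = "walsh"
    sampling_ratio: float = 1.0


@dataclass
class InstrumentSection:
    gain: float = 0.01
    adc_bits: int = 16
    adc_full_scale: float = 10.0
    additive_sd: float = 0.5 * 10.0 / 2 ** 16
    shot_scale: float = 0.0
    dark_offset: float = 0.0


@dataclass
class CsSection:
    lambda_l1: float = 0.01
    mu_tv: float = 0.1
    max_iter: int = 500
    tol: float = 1.0e-6


@dataclass
class TofSection:
    t_max_ps: float = 2000.0
    dt_ps: float = 1.0
    c_mm_ps: float = 0.2219
    sg_window: int = 11
    thickness_mm: float = 3.0


@dataclass
class DetectSection:
    threshold: float = 0.7
    min_area_px: int = 5
    connectivity: int = 8
    reference_floor: float = 1.0e-6


@dataclass
class PhantomSection:
    image_side: int = 32
    contaminated_fraction: float = 0.5
    n_samples: int = 100
    insect_length_mm: float = 3.0
    insect_width_mm: float = 1.3
    band_transmittance_chocolate: list = field(default_factory=lambda: [0.10, 0.15, 0.20])
    insect_extra_absorbance: list = field(default_factory=lambda: [0.15, 0.25, 0.60])
    tilt_gradient: float = 0.0
    texture_sd: float = 0.005
    speck_count_min: int = 3
    speck_count_poisson: float = 5.0
    speck_absorbance: list = field(default_factory=lambda: [0.1, 0.35])


@dataclass
class RunConfig:
    patterns: PatternsSection = field(default_factory=PatternsSection)
    instrument: InstrumentSection = field(default_factory=InstrumentSection)
    cs: CsSection = field(default_factory=CsSection)
    tof: TofSection = field(default_factory=TofSection)
    detect: DetectSection = field(default_factory=DetectSection)
    phantom: PhantomSection = field(default_factory=PhantomSection)
    seed: int = 12345

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fill_section(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown configuration key: {path}.{key}" if path else
                          f"unknown configuration key: {key}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from a nested dict, rejecting unknown keys with their path."""
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    sections = {f.name: f for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - set(sections)
    if unknown:
        raise ConfigError(f"unknown configuration key: {sorted(unknown)[0]}")
    kwargs = {}
    for name, f in sections.items():
        if name not in data:
            continue
        if name == "seed":
            kwargs["seed"] = int(data["seed"])
            continue
        sub = data[name]
        if not isinstance(sub, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _fill_section(f.default_factory, sub, name)  # type: ignore[misc]
    return RunConfig(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; a missing path yields the shipped defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    return config_from_dict(raw)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
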