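"""Runtime configuration with documented, field-standard defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

__all__ = ["Config", "load_config"]


@dataclass
class Config:
    """Thresholds and tolerances for the SST workflow.

    Defaults: 3 ppm maximum mass deviation (the accepted accuracy limit
    for high-resolution screening), sign-test alpha 0.05 for the
    bias-randomness criterion, +/-10 ppm EIC extraction window (wide
    enough that a drifted-but-failing peak is still measured), 1.5 ppm
    within-pair outlier gap for the two-injection protocol, 20 minutes
    per injection for time conversion, 100 injections (~33 h) as the
    batch-length warning limit, and 0.3 ppm rms as the calibration
    quality threshold.
    """

    panel_path: str | None = None
    threshold_ppm: float = 3.0
    threshold_mode: str = "each"  # each | mean
    bias_alpha: float = 0.05
    tol_ppm: float = 10.0
    min_intensity: float = 1e4
    adaptive_delta_ppm: float = 1.5
    minutes_per_injection: float = 20.0
    max_batch_injections: int = 100
    cal_rms_threshold: float = 0.3
    history_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "threshold_ppm",
            "bias_alpha",
            "tol_ppm",
            "adaptive_delta_ppm",
            "minutes_per_injection",
            "cal_rms_threshold",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.threshold_mode not in ("each", "mean"):
            raise ValueError("threshold_mode must be 'each' or 'mean'")

    def with_overrides(self, overrides: dict) -> "Config":
        values = dataclasses.asdict(self)
        unknown = set(overrides) - set(values)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(overrides)
        return Config(**values)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _coerce(current, raw: str):
    if isinstance(current, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(current, int) and not isinstance(current, bool):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    return raw


def load_config(path: str | None = None, set_overrides: tuple[str, ...] = ()) -> Config:
    """Build a Config from an optional YAML file plus ``key=value`` overrides."""
    config = Config()
    if path:
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        config = config.with_overrides(data)
    parsed = {}
    for item in set_overrides:
        if "=" not in item:
            raise ValueError(f"--set expects key=value, got {item!r}")
        key, raw = item.split("=", 1)
        current = getattr(config, key, None)
        if not hasattr(config, key):
            raise ValueError(f"unknown config key {key!r}")
        parsed[key] = _coerce(current, raw)
    return config.with_overrides(parsed) if parsed else config
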