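"""Pipeline configuration: defaults, YAML round-trip, invariant checks.

Defaults encode the study constants: 4-s classification windows at 31.25 Hz,
bout-duration classes short <= 8 s / medium 12-28 s / long >= 32 s, alpha 0.05
for all rank-sum testing, and a 95% explained-variance PCA cut for the
feature-based classifiers.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import ConfigurationError

log = logging.getLogger("msgait")

#: stride/bout validity ranges used by filter_valid.  The study removed bouts
#: with "physiologically impossible" values without printing ranges; these are
#: this package's own, stated explicitly.
DEFAULT_VALIDITY_RANGES = {
    "stride_time_s": (0.5, 3.0),
    "duty_factor": (0.45, 0.85),
    "stance_time_s": (0.1, float("inf")),
    "swing_time_s": (0.1, float("inf")),
}


@dataclass
class DurationClassBounds:
    short_max_s: float = 8.0
    medium_min_s: float = 12.0
    medium_max_s: float = 28.0
    long_min_s: float = 32.0


@dataclass
class PipelineConfig:
    window_s: float = 4.0
    fs_target: float = 31.25
    duration_class_bounds: DurationClassBounds = field(default_factory=DurationClassBounds)
    alpha: float = 0.05
    pca_variance: float = 0.95
    seed: int = 0
    validity_ranges: dict = field(default_factory=lambda: dict(DEFAULT_VALIDITY_RANGES))

    def __post_init__(self) -> None:
        b = self.duration_class_bounds
        if isinstance(b, dict):
            b = self.duration_class_bounds = DurationClassBounds(**b)
        if not (b.short_max_s < b.medium_min_s <= b.medium_max_s < b.long_min_s):
            raise ConfigurationError(
                "duration class bounds must satisfy "
                "short_max_s < medium_min_s <= medium_max_s < long_min_s; got "
                f"{b.short_max_s}, {b.medium_min_s}, {b.medium_max_s}, {b.long_min_s}"
            )
        if not (0 < self.pca_variance <= 1):
            raise ConfigurationError(f"pca_variance must be in (0, 1], got {self.pca_variance}")
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.window_s <= 0 or self.fs_target <= 0:
            raise ConfigurationError("window_s and fs_target must be positive")
        self.validity_ranges = {k: tuple(v) for k, v in self.validity_ranges.items()}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["validity_ranges"] = {k: list(v) for k, v in self.validity_ranges.items()}
        return d


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a config from YAML (or defaults when *path* is None/empty).

    Explicit keyword overrides win over file values; the resulting config is
    echoed to the package logger.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigurationError(f"config file {path} must hold a mapping")
            data.update(loaded)
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    log.info("config: %s", cfg.to_dict())
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
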