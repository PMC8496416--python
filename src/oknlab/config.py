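"""Detector configuration shared by the offline and live OKN analyses."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
import yaml

from .errors import ConfigError

__all__ = ["DetectorConfig"]


@dataclass
class DetectorConfig:
    """Tunable parameters of the OKN detection pipeline.

    Defaults follow the reference measurement protocol: velocity-threshold
    quick-phase detection with noise multiplier ``lambda_noise = 7``, a
    34-frame (283 ms at 120 Hz) noise-estimation window, a 50 ms minimum
    separation between saccades in the offline analysis, blink removal with
    a 50 ms buffer (offline only), 5-sample moving-average smoothing and a
    ~17 ms trim on both sides of every candidate slow phase, and a trial
    declared "seen" once ``robust_count`` slow phases in the stimulus
    direction have been validated, within a 4 s timeout.

    The slow-phase velocity threshold has no published reference value; the
    0.5 deg/s default is a deliberately conservative fraction of the
    stimulus speed and should be reviewed for other stimulus velocities.
    """

    lambda_noise: float = 7.0
    noise_window_frames: int = 34
    frame_rate_hz: float = 120.0
    smooth_window_samples: int = 5
    trim_ms: float = 17.0
    sp_velocity_threshold_dps: float = 0.5
    robust_count: int = 2
    timeout_s: float = 4.0
    blink_buffer_ms: float = 50.0
    min_saccade_separation_ms: float = 50.0   # offline; overshoot protection
    live_min_saccade_separation_ms: float = 0.0
    min_saccade_duration_ms: float = 6.0      # offline, 1000 Hz convention
    live_min_saccade_frames: int = 2
    binocular_required: bool = True
    sp_velocity_estimator: str = "endpoint"   # or "mean_sample"
    live_full_rate: bool = False              # analyze live at tracker rate

    def __post_init__(self) -> None:
        if self.lambda_noise <= 0:
            raise ConfigError("lambda_noise must be positive")
        if self.noise_window_frames < 5:
            raise ConfigError("noise_window_frames must allow >=5 velocities")
        if self.sp_velocity_estimator not in ("endpoint", "mean_sample"):
            raise ConfigError(
                f"unknown sp_velocity_estimator {self.sp_velocity_estimator!r}"
            )
        if self.robust_count < 1:
            raise ConfigError("robust_count must be >= 1")

    @property
    def noise_window_ms(self) -> float:
        return self.noise_window_frames / self.frame_rate_hz * 1000.0

    @property
    def live_min_saccade_duration_ms(self) -> float:
        return self.live_min_saccade_frames / self.frame_rate_hz * 1000.0

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown detector config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "DetectorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "detector" in data:
            data = data["detector"]
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"detector": self.to_dict()}, fh, sort_keys=False)
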