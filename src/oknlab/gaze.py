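"""Core gaze-recording data model.

A recording is a binocular time series of horizontal/vertical gaze positions
(degrees of visual angle, rightward positive) and a per-eye pupil signal.
A pupil value of zero, a NaN pupil, or a non-finite position marks a
track-lost (blink) sample.  Positions are stored in degrees throughout the
package because every detection threshold downstream is angular (deg/s).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np

from .errors import DataError

__all__ = ["GazeSample", "GazeTrace", "TrialRecord"]


class GazeSample(NamedTuple):
    """One binocular gaze sample (convenience view; arrays are primary)."""

    t: float
    x_left: float
    y_left: float
    x_right: float
    y_right: float
    pupil_left: float
    pupil_right: float


@dataclass
class GazeTrace:
    """Binocular gaze recording with a nominal sampling rate.

    Parameters
    ----------
    t:
        Timestamps in milliseconds, strictly increasing.
    x_left, y_left, x_right, y_right:
        Gaze position per eye in degrees of visual angle.
    pupil_left, pupil_right:
        Non-negative pupil signal; ``0`` or NaN encodes track loss.
    rate_hz:
        Nominal sampling rate (1000 Hz for the reference eye tracker,
        120 Hz for frame-coupled live series).
    meta:
        Free-form provenance (source file, trial id, simulator ground truth).
    """

    t: np.ndarray
    x_left: np.ndarray
    y_left: np.ndarray
    x_right: np.ndarray
    y_right: np.ndarray
    pupil_left: np.ndarray
    pupil_right: np.ndarray
    rate_hz: float
    meta: dict = field(default_factory=dict)

    _ARRAY_FIELDS = (
        "t",
        "x_left",
        "y_left",
        "x_right",
        "y_right",
        "pupil_left",
        "pupil_right",
    )

    def __post_init__(self) -> None:
        for name in self._ARRAY_FIELDS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        for name in self._ARRAY_FIELDS:
            if getattr(self, name).size != n:
                raise DataError(f"field {name!r} has length "
                                f"{getattr(self, name).size}, expected {n}")
        dt = np.diff(self.t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            # report the 1-based row of the second of the offending pair
            raise DataError(
                f"timestamps not strictly increasing at sample {bad[0] + 2}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.t.size)

    def __len__(self) -> int:
        return self.n

    @property
    def duration_ms(self) -> float:
        """Nominal covered duration (sample count over nominal rate)."""
        return self.n * 1000.0 / self.rate_hz

    @property
    def track_lost(self) -> np.ndarray:
        """Boolean mask of blink / track-loss samples (either eye)."""
        lost = np.zeros(self.n, dtype=bool)
        for p in (self.pupil_left, self.pupil_right):
            lost |= ~np.isfinite(p) | (p <= 0)
        for x in (self.x_left, self.x_right):
            lost |= ~np.isfinite(x)
        return lost

    # -- manipulation ---------------------------------------------------
    def copy(self) -> "GazeTrace":
        return GazeTrace(
            *(getattr(self, f).copy() for f in self._ARRAY_FIELDS),
            rate_hz=self.rate_hz,
            meta=dict(self.meta),
        )

    def slice(self, i0: int, i1: int) -> "GazeTrace":
        """Sub-trace over sample indices ``[i0, i1)``."""
        return GazeTrace(
            *(getattr(self, f)[i0:i1] for f in self._ARRAY_FIELDS),
            rate_hz=self.rate_hz,
            meta=dict(self.meta),
        )

    def mirrored(self) -> "GazeTrace":
        """Left-right reflected copy (horizontal positions negated)."""
        out = self.copy()
        out.x_left = -out.x_left
        out.x_right = -out.x_right
        return out

    def samples(self) -> Iterator[GazeSample]:
        for i in range(self.n):
            yield GazeSample(
                self.t[i],
                self.x_left[i],
                self.y_left[i],
                self.x_right[i],
                self.y_right[i],
                self.pupil_left[i],
                self.pupil_right[i],
            )

    def equals(self, other: "GazeTrace") -> bool:
        """Exact array equality (NaNs compare equal), ignoring meta."""
        return all(
            np.array_equal(getattr(self, f), getattr(other, f), equal_nan=True)
            for f in self._ARRAY_FIELDS
        )


@dataclass
class TrialRecord:
    """One completed trial: stimulus, decision, and the detected events.

    ``outcome`` is ``"seen"`` or ``"not_seen"``; ``abort_time_ms`` is the
    time of the robust-OKN decision (early abort) or the timeout.  A
    "seen" outcome requires at least ``robust_count`` validated slow
    phases among the recorded events.
    """

    trial_id: str
    stimulus: object            # StimulusSpec (kept loose to avoid a cycle)
    outcome: str
    abort_time_ms: float
    events: list = field(default_factory=list)
    robust_count: int = 2

    def __post_init__(self) -> None:
        if self.outcome not in ("seen", "not_seen"):
            raise DataError(f"invalid outcome {self.outcome!r}")
        n_slow = sum(
            1 for e in self.events
            if getattr(e, "direction_match", None) is True
        )
        if self.outcome == "seen" and n_slow < self.robust_count:
            raise DataError(
                f"'seen' outcome requires >= {self.robust_count} validated "
                f"slow phases, got {n_slow}"
            )
        timeout_ms = getattr(self.stimulus, "duration_max_s", None)
        if timeout_ms is not None and self.abort_time_ms > timeout_ms * 1000.0 + 1e-6:
            raise DataError("abort_time_ms exceeds the trial timeout")

    @classmethod
    def from_detection(
        cls, trial_id: str, stimulus, result, robust_count: int = 2
    ) -> "TrialRecord":
        """Build a record from a detector's ``DetectionResult``."""
        return cls(
            trial_id=trial_id,
            stimulus=stimulus,
            outcome="seen" if result.okn_present else "not_seen",
            abort_time_ms=result.decision_time_ms,
            events=list(result.saccades) + list(result.slow_phases),
            robust_count=robust_count,
        )
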