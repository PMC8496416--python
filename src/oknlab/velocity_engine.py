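"""Velocity transform, median-based noise threshold, and velocity-threshold
event detection shared by the offline and live OKN detectors.

The velocity estimate is the classic five-point moving-window transform used
for velocity-based (micro)saccade detection,

    v_n = (x_{n+2} + x_{n+1} - x_{n-1} - x_{n-2}) / (6 dt),

which is exact for affine position signals and suppresses high-frequency
sensor noise.  The per-eye noise scale is the median-based estimator

    sigma^2 = median((v - median(v))^2),

robust against the saccades contained in the estimation window, and the
detection threshold is ``eta = lambda * sigma`` (lambda defaults to 7).
Only the horizontal component is analyzed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import InsufficientDataError, NoiseEstimationError
from .gaze import GazeTrace

__all__ = [
    "VelocityTrace",
    "NoiseThreshold",
    "SaccadeEvent",
    "compute_velocity",
    "noise_threshold",
    "detect_saccades",
    "mask_blinks",
]


@dataclass
class VelocityTrace:
    """Horizontal velocity per eye in deg/s, NaN over kernel margins and
    blink-masked samples."""

    t: np.ndarray
    v_left: np.ndarray
    v_right: np.ndarray
    rate_hz: float


@dataclass
class NoiseThreshold:
    """Per-eye median-based velocity noise scale and detection threshold."""

    sigma_left: float
    sigma_right: float
    lambda_noise: float

    @property
    def eta_left(self) -> float:
        return self.lambda_noise * self.sigma_left

    @property
    def eta_right(self) -> float:
        return self.lambda_noise * self.sigma_right


@dataclass
class SaccadeEvent:
    """A detected quick phase: closed interval of supra-threshold samples."""

    t_start: float
    t_end: float
    i_start: int
    i_end: int
    peak_velocity: float  # signed, deg/s
    direction: int        # sign of the peak velocity
    binocular: bool

    @property
    def duration_ms(self) -> float:
        return self.t_end - self.t_start


def _five_point_velocity(x: np.ndarray, dt_s: float) -> np.ndarray:
    v = np.full(x.shape, np.nan)
    if x.size >= 5:
        v[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt_s)
    # the kernel skips the center sample; a blink-masked position must
    # still yield a masked velocity
    v[~np.isfinite(x)] = np.nan
    return v


def compute_velocity(trace: GazeTrace) -> VelocityTrace:
    """Five-point horizontal velocity transform of a binocular trace.

    The first and last two samples are NaN (kernel margin); NaN positions
    (blinks / masked samples) contaminate velocities within the kernel
    support, which is the desired masking behaviour downstream.
    """
    if trace.n < 5:
        raise InsufficientDataError(
            f"velocity needs >=5 samples, got {trace.n}"
        )
    dt_s = 1.0 / trace.rate_hz
    return VelocityTrace(
        t=trace.t,
        v_left=_five_point_velocity(trace.x_left, dt_s),
        v_right=_five_point_velocity(trace.x_right, dt_s),
        rate_hz=trace.rate_hz,
    )


def _median_sigma(v: np.ndarray) -> float:
    """Median-based velocity SD: sqrt(median((v - median v)^2)).

    The centered form is exactly shift-invariant and homogeneous (and
    coincides with the uncentered median(v^2) - median(v)^2 variant for
    zero-median windows), and cannot collapse when a velocity offset is
    present in the window.
    """
    v = v[np.isfinite(v)]
    if v.size < 5:
        raise NoiseEstimationError(
            f"noise window has {v.size} usable velocities, need >=5"
        )
    med = float(np.median(v))
    return math.sqrt(float(np.median((v - med) ** 2)))


def noise_threshold(
    v: VelocityTrace,
    window: Optional[Tuple[int, int]] = None,
    lambda_noise: float = 7.0,
) -> NoiseThreshold:
    """Median-based noise scale per eye over a sample-index window.

    ``window`` is a half-open index range ``(i0, i1)``; ``None`` uses the
    whole trace.  Raises :class:`NoiseEstimationError` when fewer than five
    finite velocities remain in the window for an eye.
    """
    i0, i1 = window if window is not None else (0, v.t.size)
    return NoiseThreshold(
        sigma_left=_median_sigma(v.v_left[i0:i1]),
        sigma_right=_median_sigma(v.v_right[i0:i1]),
        lambda_noise=lambda_noise,
    )


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs of True as inclusive index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_saccades(
    v: VelocityTrace,
    eta: NoiseThreshold,
    min_duration_ms: float = 6.0,
    min_separation_ms: float = 0.0,
    binocular_required: bool = True,
    start: int = 0,
    end: Optional[int] = None,
) -> List[SaccadeEvent]:
    """Velocity-threshold saccade (OKN quick-phase) detection.

    A monocular run is a maximal stretch of samples with ``|v| > eta`` for
    that eye, kept if it spans at least ``min_duration_ms``.  With
    ``binocular_required`` a run survives only if it overlaps (by >= 1
    sample) a surviving run of the other eye, and overlapping runs are
    reported as their merged (union) interval.  Finally, events separated
    by less than ``min_separation_ms`` are merged into one — the overshoot
    protection of the offline analysis.  ``start``/``end`` restrict the
    scanned index range.
    """
    n = v.t.size
    end = n if end is None else end
    dt_ms = 1000.0 / v.rate_hz
    min_samples = max(1, int(math.ceil(min_duration_ms / dt_ms - 1e-9)))

    def eye_runs(vel: np.ndarray, thr: float) -> List[Tuple[int, int]]:
        mask = np.zeros(n, dtype=bool)
        seg = vel[start:end]
        with np.errstate(invalid="ignore"):
            mask[start:end] = np.abs(seg) > thr
        mask[~np.isfinite(v.t)] = False
        runs = _runs(mask)
        return [(a, b) for a, b in runs if b - a + 1 >= min_samples]

    runs_l = eye_runs(v.v_left, eta.eta_left)
    runs_r = eye_runs(v.v_right, eta.eta_right)

    def overlaps(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
        return a[0] <= b[1] and b[0] <= a[1]

    if binocular_required:
        kept = [r for r in runs_l if any(overlaps(r, s) for s in runs_r)]
        kept += [r for r in runs_r if any(overlaps(r, s) for s in runs_l)]
    else:
        kept = runs_l + runs_r

    if not kept:
        return []

    # merge overlapping/adjacent index intervals into single events
    kept.sort()
    merged: List[List[int]] = [list(kept[0])]
    for a, b in kept[1:]:
        if a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    # merge events closer than min_separation_ms
    events: List[List[int]] = [merged[0]]
    for a, b in merged[1:]:
        gap_ms = v.t[a] - v.t[events[-1][1]]
        if gap_ms < min_separation_ms:
            events[-1][1] = b
        else:
            events.append([a, b])

    out: List[SaccadeEvent] = []
    for a, b in events:
        seg_l = v.v_left[a : b + 1]
        seg_r = v.v_right[a : b + 1]
        vals = np.concatenate([seg_l[np.isfinite(seg_l)], seg_r[np.isfinite(seg_r)]])
        peak = float(vals[np.argmax(np.abs(vals))]) if vals.size else 0.0
        bino = any(overlaps((a, b), r) for r in runs_l) and any(
            overlaps((a, b), r) for r in runs_r
        )
        out.append(
            SaccadeEvent(
                t_start=float(v.t[a]),
                t_end=float(v.t[b]),
                i_start=int(a),
                i_end=int(b),
                peak_velocity=peak,
                direction=int(np.sign(peak)) if peak else 0,
                binocular=bool(bino),
            )
        )
    return out


def mask_blinks(trace: GazeTrace, buffer_ms: float = 50.0) -> GazeTrace:
    """Invalidate track-lost runs extended by ``buffer_ms`` on each side.

    Every maximal run of blink samples is dilated in time by the buffer;
    positions over the dilated interval become NaN and pupil signals 0, so
    velocities over those samples are NaN downstream.  A trace without
    blinks is returned unchanged (as a copy).
    """
    if buffer_ms < 0:
        raise ValueError("buffer_ms must be >= 0")
    lost = trace.track_lost
    out = trace.copy()
    if not lost.any():
        return out
    invalid = np.zeros(trace.n, dtype=bool)
    for a, b in _runs(lost):
        lo = trace.t[a] - buffer_ms
        hi = trace.t[b] + buffer_ms
        invalid |= (trace.t >= lo) & (trace.t <= hi)
    for name in ("x_left", "y_left", "x_right", "y_right"):
        arr = getattr(out, name)
        arr[invalid] = np.nan
    out.pupil_left[invalid] = 0.0
    out.pupil_right[invalid] = 0.0
    out.meta["blink_mask"] = invalid
    return out
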