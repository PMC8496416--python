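"""Post-hoc (offline) OKN analysis of a recorded trial at the full tracker
sampling rate: blink removal with a 50 ms buffer, velocity-threshold quick-
phase detection with a 50 ms minimum saccade separation, slow-phase
validation of every inter-saccadic gap, and the robust-OKN decision
(at least two validated slow phases in the stimulus direction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .config import DetectorConfig
from .errors import NoiseEstimationError
from .gaze import GazeTrace
from .stimulus_geometry import StimulusSpec
from .velocity_engine import (
    NoiseThreshold,
    SaccadeEvent,
    VelocityTrace,
    compute_velocity,
    detect_saccades,
    mask_blinks,
    noise_threshold,
)

__all__ = ["SlowPhaseEvent", "DetectionResult", "validate_slow_phase",
           "analyze_trial_offline"]


@dataclass
class SlowPhaseEvent:
    """A validated OKN slow phase (inter-saccadic tracking segment)."""

    t_start: float
    t_end: float
    mean_velocity: float   # deg/s on the smoothed segment
    direction_match: bool


@dataclass
class DetectionResult:
    """Outcome of an OKN analysis of one trial."""

    okn_present: bool
    n_valid_slow_phases: int
    saccades: List[SaccadeEvent]
    slow_phases: List[SlowPhaseEvent]
    decision_time_ms: float


def _smooth_valid(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; output aligned to x[h : n-h] (h = window//2).

    Windows containing NaN yield NaN.
    """
    if window <= 1:
        return x.copy()
    kernel = np.full(window, 1.0 / window)
    return np.convolve(x, kernel, mode="valid")


def validate_slow_phase(
    t: np.ndarray,
    x_left: np.ndarray,
    x_right: np.ndarray,
    stimulus_direction: int,
    config: DetectorConfig,
) -> Optional[SlowPhaseEvent]:
    """Validate a candidate slow phase between two detected saccades.

    The segment (arrays cover exactly the inter-saccadic gap) is shrunk by
    ``trim_ms`` at both ends to discard saccadic overshoot, the horizontal
    position is smoothed with a centered ``smooth_window_samples`` moving
    average, and the mean velocity is the endpoint displacement of the
    smoothed signal over its duration (per eye, averaged over eyes with
    usable data; the ``mean_sample`` estimator averages the sample-to-sample
    slopes instead).  The event is returned only when the velocity sign
    matches the stimulus drift direction and its magnitude reaches
    ``sp_velocity_threshold_dps``; segments too short to survive trimming
    plus smoothing yield ``None``.
    """
    n = t.size
    if n < 2:
        return None
    keep = (t >= t[0] + config.trim_ms) & (t <= t[-1] - config.trim_ms)
    if keep.sum() < max(config.smooth_window_samples, 2):
        return None
    tt = t[keep]

    velocities = []
    for x in (x_left, x_right):
        xs = _smooth_valid(x[keep], config.smooth_window_samples)
        h = (config.smooth_window_samples - 1) // 2 if config.smooth_window_samples > 1 else 0
        ts = tt[h : tt.size - h] if h else tt
        finite = np.isfinite(xs)
        if finite.sum() < 2:
            continue
        idx = np.flatnonzero(finite)
        if config.sp_velocity_estimator == "endpoint":
            a, b = idx[0], idx[-1]
            if ts[b] <= ts[a]:
                continue
            velocities.append((xs[b] - xs[a]) / ((ts[b] - ts[a]) / 1000.0))
        else:  # mean_sample
            dv = np.diff(xs[idx]) / (np.diff(ts[idx]) / 1000.0)
            if dv.size == 0:
                continue
            velocities.append(float(np.mean(dv)))
    if not velocities:
        return None
    mean_v = float(np.mean(velocities))
    match = math.copysign(1.0, mean_v) == float(stimulus_direction)
    if not match or abs(mean_v) < config.sp_velocity_threshold_dps:
        return None
    return SlowPhaseEvent(
        t_start=float(tt[0]),
        t_end=float(tt[-1]),
        mean_velocity=mean_v,
        direction_match=True,
    )


def _slow_phases_between(
    trace: GazeTrace,
    saccades: Sequence[SaccadeEvent],
    stimulus_direction: int,
    config: DetectorConfig,
) -> List[SlowPhaseEvent]:
    out: List[SlowPhaseEvent] = []
    for prev, nxt in zip(saccades[:-1], saccades[1:]):
        g0, g1 = prev.i_end + 1, nxt.i_start  # half-open
        if g1 - g0 < 2:
            continue
        ev = validate_slow_phase(
            trace.t[g0:g1],
            trace.x_left[g0:g1],
            trace.x_right[g0:g1],
            stimulus_direction,
            config,
        )
        if ev is not None:
            out.append(ev)
    return out


def analyze_trial_offline(
    trace: GazeTrace,
    stimulus: StimulusSpec,
    config: Optional[DetectorConfig] = None,
) -> DetectionResult:
    """Full-rate post-hoc OKN analysis of one trial.

    Pipeline: blink masking (50 ms buffer) -> five-point velocity ->
    median-based noise threshold over the configured noise window (the same
    first ~283 ms used by the live method, for comparability) -> saccade
    detection with the 50 ms minimum separation -> slow-phase validation of
    every inter-saccadic gap -> robust-OKN decision.  Fewer than two
    detected saccades is not an error: it simply yields ``okn_present =
    False`` with zero valid slow phases.

    ``decision_time_ms`` is the onset time of the saccade closing the
    ``robust_count``-th valid slow phase (the moment the live method would
    abort), or the end of the analyzed window otherwise.
    """
    config = config or DetectorConfig()
    masked = mask_blinks(trace, config.blink_buffer_ms)
    vt = compute_velocity(masked)
    nw = int(round(config.noise_window_ms * trace.rate_hz / 1000.0))
    nw = min(max(nw, 5), trace.n)
    try:
        nt = noise_threshold(vt, (0, nw), config.lambda_noise)
    except NoiseEstimationError:
        # blink-dominated noise window: no threshold can be fixed, hence
        # nothing can be detected in this trial
        return DetectionResult(
            okn_present=False,
            n_valid_slow_phases=0,
            saccades=[],
            slow_phases=[],
            decision_time_ms=float(trace.t[-1]),
        )
    saccades = detect_saccades(
        vt,
        nt,
        min_duration_ms=config.min_saccade_duration_ms,
        min_separation_ms=config.min_saccade_separation_ms,
        binocular_required=config.binocular_required,
    )
    if len(saccades) < 2:
        return DetectionResult(
            okn_present=False,
            n_valid_slow_phases=0,
            saccades=list(saccades),
            slow_phases=[],
            decision_time_ms=float(trace.t[-1]),
        )
    slow = _slow_phases_between(masked, saccades, stimulus.direction, config)
    present = len(slow) >= config.robust_count
    if present:
        closing_t = slow[config.robust_count - 1].t_end
        nxt = [s.t_start for s in saccades if s.t_start >= closing_t]
        decision_t = float(nxt[0]) if nxt else float(closing_t)
    else:
        decision_t = float(trace.t[-1])
    return DetectionResult(
        okn_present=present,
        n_valid_slow_phases=len(slow),
        saccades=list(saccades),
        slow_phases=slow,
        decision_time_ms=decision_t,
    )
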