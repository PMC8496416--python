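"""Streaming OKN detection coupled to the display frame rate (120 Hz).

The live method analyses one representative gaze sample per display frame.
The first ``noise_window_frames`` frames (34 frames, ~283 ms) are used only
to fix the per-eye velocity-noise threshold; afterwards the same five-point
velocity transform and threshold test run incrementally on the frame-rate
series.  Whenever the start of a new saccade is confirmed, the preceding
inter-saccadic segment is validated as a slow phase, and the trial is
aborted with the decision "seen" the moment ``robust_count`` slow phases in
the stimulus direction have been validated; otherwise "not seen" is emitted
at the timeout.  Deliberately, no blink handling exists in live mode (a
known limitation of the live protocol, kept so that live/offline
discordance patterns are reproducible); non-finite samples simply yield
NaN velocities.

Analysis is strictly causal: with the five-point kernel the velocity of
frame ``j`` becomes available two frames later, so the detection latency
floor is two frames (~17 ms).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .config import DetectorConfig
from .errors import NoiseEstimationError
from .gaze import GazeTrace
from .offline_detector import DetectionResult, SlowPhaseEvent, validate_slow_phase
from .stimulus_geometry import StimulusSpec
from .velocity_engine import (
    NoiseThreshold,
    SaccadeEvent,
    VelocityTrace,
    _runs,
    detect_saccades,
    noise_threshold,
)

__all__ = [
    "LiveState",
    "LiveDetector",
    "downsample_to_frames",
    "detect_live",
    "replay_compare",
]


def downsample_to_frames(trace: GazeTrace, frame_rate_hz: float) -> GazeTrace:
    """One representative sample per display frame (latest-sample policy).

    Frame ``k`` carries the most recent tracker sample at or before the
    frame boundary ``t0 + k / frame_rate``; the frame series is stamped on
    the nominal frame grid.  A trace already at the frame rate is returned
    unchanged; an empty trace yields an empty series.
    """
    if abs(trace.rate_hz - frame_rate_hz) < 1e-6 * frame_rate_hz:
        return trace
    if trace.rate_hz < frame_rate_hz:
        raise ValueError("trace rate below frame rate")
    period_ms = 1000.0 / frame_rate_hz
    n_frames = int(math.floor(trace.duration_ms / period_ms + 1e-9))
    t0 = trace.t[0]
    boundaries = t0 + np.arange(n_frames) * period_ms
    idx = np.searchsorted(trace.t, boundaries + 1e-9, side="right") - 1
    idx = np.clip(idx, 0, trace.n - 1)
    return GazeTrace(
        t=boundaries,
        x_left=trace.x_left[idx],
        y_left=trace.y_left[idx],
        x_right=trace.x_right[idx],
        y_right=trace.y_right[idx],
        pupil_left=trace.pupil_left[idx],
        pupil_right=trace.pupil_right[idx],
        rate_hz=frame_rate_hz,
        meta={**trace.meta, "downsampled_from_hz": trace.rate_hz},
    )


@dataclass
class LiveState:
    """Introspectable snapshot of the streaming detector."""

    phase: str                       # "noise_estimation" | "scanning"
    frames_seen: int
    noise: Optional[NoiseThreshold]
    last_saccade_end: Optional[float]
    open_saccade: Optional[Tuple[float, Optional[float]]]
    valid_slow_phases: int
    decided: bool
    decision: Optional[bool]         # True = seen
    decision_time_ms: Optional[float]


def _prefix_events_and_slow_phases(
    t: np.ndarray,
    xl: np.ndarray,
    xr: np.ndarray,
    nt: NoiseThreshold,
    stimulus_direction: int,
    config: DetectorConfig,
):
    """Causal analysis of a frame-series prefix.

    Returns (saccades, slow_phases) where the last saccade may still be
    open (its start is confirmed once it spans the minimum frame count; the
    velocity of frame j is computable only once frame j+2 has arrived,
    which the prefix length encodes by construction).
    """
    n = t.size
    dt_s = 1.0 / config.frame_rate_hz
    v = np.full((2, n), np.nan)
    for row, x in enumerate((xl, xr)):
        if n >= 5:
            v[row, 2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt_s)
        v[row, ~np.isfinite(x)] = np.nan
    vt = VelocityTrace(t=t, v_left=v[0], v_right=v[1],
                       rate_hz=config.frame_rate_hz)
    saccades = detect_saccades(
        vt,
        nt,
        min_duration_ms=config.live_min_saccade_duration_ms,
        min_separation_ms=config.live_min_saccade_separation_ms,
        binocular_required=config.binocular_required,
        start=config.noise_window_frames,
    )
    slow: List[SlowPhaseEvent] = []
    for prev, nxt in zip(saccades[:-1], saccades[1:]):
        g0, g1 = prev.i_end + 1, nxt.i_start
        if g1 - g0 < 2:
            continue
        ev = validate_slow_phase(
            t[g0:g1], xl[g0:g1], xr[g0:g1], stimulus_direction, config
        )
        if ev is not None:
            slow.append(ev)
    return saccades, slow


class LiveDetector:
    """Frame-by-frame OKN detector with early trial abort.

    Feed one gaze sample per display frame via :meth:`feed_frame`; the
    return value is ``None`` until a decision is reached, then a
    ``(seen, decision_time_ms)`` tuple.  Frames arriving after the decision
    are ignored with a warning.  Feeding the identical frame series twice
    (fresh instances) yields identical decisions: there is no internal
    randomness.
    """

    def __init__(
        self, stimulus: StimulusSpec, config: Optional[DetectorConfig] = None
    ) -> None:
        self.stimulus = stimulus
        self.config = config or DetectorConfig()
        self._t: List[float] = []
        self._xl: List[float] = []
        self._xr: List[float] = []
        self._noise: Optional[NoiseThreshold] = None
        self._noise_failed = False
        self._valid_slow = 0
        self._decided = False
        self._decision: Optional[bool] = None
        self._decision_time: Optional[float] = None
        self._saccades: List[SaccadeEvent] = []
        self._slow: List[SlowPhaseEvent] = []
        self._prev_supra = False

    # -- noise phase -----------------------------------------------------
    def _fit_noise(self) -> None:
        cfg = self.config
        nw = cfg.noise_window_frames
        t = np.asarray(self._t[:nw])
        dt_s = 1.0 / cfg.frame_rate_hz
        v = np.full((2, nw), np.nan)
        for row, xs in enumerate((self._xl, self._xr)):
            x = np.asarray(xs[:nw])
            v[row, 2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt_s)
            v[row, ~np.isfinite(x)] = np.nan
        vt = VelocityTrace(t=t, v_left=v[0], v_right=v[1],
                           rate_hz=cfg.frame_rate_hz)
        try:
            # restrict to velocities that depend only on the first nw frames
            self._noise = noise_threshold(vt, (0, nw - 2), cfg.lambda_noise)
        except NoiseEstimationError:
            # unusable noise window (e.g. blink-dominated): nothing can be
            # detected in this trial; it will time out as "not seen"
            self._noise_failed = True

    # -- scanning --------------------------------------------------------
    def _new_velocity_supra(self) -> bool:
        """Is the newest computable velocity sample supra-threshold?"""
        L = len(self._t)
        j = L - 3
        if j < self.config.noise_window_frames or self._noise is None:
            return False
        dt_s = 1.0 / self.config.frame_rate_hz
        out = False
        for xs, eta in (
            (self._xl, self._noise.eta_left),
            (self._xr, self._noise.eta_right),
        ):
            num = xs[j + 2] + xs[j + 1] - xs[j - 1] - xs[j - 2]
            v = num / (6.0 * dt_s) if math.isfinite(xs[j]) else math.nan
            if math.isfinite(v) and abs(v) > eta:
                out = True
        return out

    def feed_frame(
        self,
        t_ms: float,
        x_left: float,
        y_left: float,
        x_right: float,
        y_right: float,
        pupil_left: float = 1.0,
        pupil_right: float = 1.0,
    ) -> Optional[Tuple[bool, float]]:
        """Process one display frame; returns the decision when reached."""
        cfg = self.config
        if self._decided:
            warnings.warn("frame fed after decision; ignored", stacklevel=2)
            return (self._decision, self._decision_time)
        # non-finite pupil means track loss: position treated as missing
        if not (math.isfinite(pupil_left) and pupil_left > 0):
            x_left = math.nan
        if not (math.isfinite(pupil_right) and pupil_right > 0):
            x_right = math.nan
        self._t.append(float(t_ms))
        self._xl.append(float(x_left))
        self._xr.append(float(x_right))
        L = len(self._t)

        if L == cfg.noise_window_frames:
            self._fit_noise()

        if (
            L > cfg.noise_window_frames
            and self._noise is not None
            and not self._noise_failed
        ):
            supra = self._new_velocity_supra()
            # events can only appear/extend on supra-threshold samples, so
            # the prefix re-analysis is skipped on quiet frames
            if supra or self._prev_supra:
                self._rescan()
            self._prev_supra = supra
            if self._valid_slow >= cfg.robust_count:
                self._decided = True
                self._decision = True
                self._decision_time = float(t_ms)
                return (True, self._decision_time)

        elapsed = t_ms - self._t[0]
        if elapsed >= cfg.timeout_s * 1000.0 - 1e-9:
            return self.finalize()
        return None

    def finalize(self) -> Tuple[bool, float]:
        """Close the trial at the timeout if no decision was reached.

        The streaming clock only advances with fed frames, so a trial whose
        last frame falls just short of the timeout boundary is closed here
        (the experiment loop calls this when the presentation clock reaches
        ``timeout_s``).
        """
        if not self._decided:
            self._decided = True
            self._decision = False
            t0 = self._t[0] if self._t else 0.0
            self._decision_time = t0 + self.config.timeout_s * 1000.0
        return (self._decision, self._decision_time)

    def _rescan(self) -> None:
        saccades, slow = _prefix_events_and_slow_phases(
            np.asarray(self._t),
            np.asarray(self._xl),
            np.asarray(self._xr),
            self._noise,
            self.stimulus.direction,
            self.config,
        )
        self._saccades = saccades
        self._slow = slow
        # the count is monotone within a trial by contract
        self._valid_slow = max(self._valid_slow, len(slow))

    # -- introspection ---------------------------------------------------
    @property
    def state(self) -> LiveState:
        L = len(self._t)
        open_sac = None
        last_end = None
        if self._saccades:
            last = self._saccades[-1]
            if last.i_end >= L - 3:  # still touching the causal frontier
                open_sac = (last.t_start, None)
                if len(self._saccades) > 1:
                    last_end = self._saccades[-2].t_end
            else:
                last_end = last.t_end
        return LiveState(
            phase=(
                "noise_estimation"
                if L < self.config.noise_window_frames
                else "scanning"
            ),
            frames_seen=L,
            noise=self._noise,
            last_saccade_end=last_end,
            open_saccade=open_sac,
            valid_slow_phases=self._valid_slow,
            decided=self._decided,
            decision=self._decision,
            decision_time_ms=self._decision_time,
        )

    def result(self) -> DetectionResult:
        return DetectionResult(
            okn_present=bool(self._decision),
            n_valid_slow_phases=self._valid_slow,
            saccades=list(self._saccades),
            slow_phases=list(self._slow),
            decision_time_ms=(
                self._decision_time
                if self._decision_time is not None
                else (self._t[-1] if self._t else 0.0)
            ),
        )


def detect_live(
    trace: GazeTrace,
    stimulus: StimulusSpec,
    config: Optional[DetectorConfig] = None,
) -> DetectionResult:
    """Batch replay of the live method on a recorded trace.

    The trace is decimated to the display frame rate (latest-sample policy)
    unless ``config.live_full_rate`` keeps the tracker rate, and the exact
    streaming semantics are reproduced: the noise threshold is fixed from
    the first 34 frames, events confirm only once their velocities are
    causally available (two-frame lookahead), and the decision time equals
    the frame at which the ``robust_count``-th slow phase was validated, or
    the timeout.  Equivalence with :class:`LiveDetector` is asserted in the
    test suite.
    """
    config = config or DetectorConfig()
    if config.live_full_rate:
        frames = trace
        frame_rate = trace.rate_hz
        cfg = config
    else:
        frames = downsample_to_frames(trace, config.frame_rate_hz)
        frame_rate = config.frame_rate_hz
        cfg = config
    timeout_ms = cfg.timeout_s * 1000.0
    t0 = frames.t[0] if frames.n else 0.0
    keep = frames.t - t0 <= timeout_ms + 1e-9
    frames = frames.slice(0, int(np.count_nonzero(keep)))
    n = frames.n
    nw = cfg.noise_window_frames
    timeout_decision = DetectionResult(
        okn_present=False,
        n_valid_slow_phases=0,
        saccades=[],
        slow_phases=[],
        decision_time_ms=t0 + timeout_ms,
    )
    if n <= nw:
        return timeout_decision

    xl = np.where(
        np.isfinite(frames.pupil_left) & (frames.pupil_left > 0),
        frames.x_left,
        np.nan,
    )
    xr = np.where(
        np.isfinite(frames.pupil_right) & (frames.pupil_right > 0),
        frames.x_right,
        np.nan,
    )

    dt_s = 1.0 / frame_rate
    v = np.full((2, n), np.nan)
    for row, x in enumerate((xl, xr)):
        v[row, 2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt_s)
        v[row, ~np.isfinite(x)] = np.nan
    vt = VelocityTrace(t=frames.t, v_left=v[0], v_right=v[1], rate_hz=frame_rate)
    try:
        nt = noise_threshold(vt, (0, nw - 2), cfg.lambda_noise)
    except NoiseEstimationError:
        return timeout_decision

    min_frames = cfg.live_min_saccade_frames
    min_dur_ms = min_frames * 1000.0 / frame_rate
    saccades = detect_saccades(
        vt,
        nt,
        min_duration_ms=min_dur_ms,
        min_separation_ms=cfg.live_min_saccade_separation_ms,
        binocular_required=cfg.binocular_required,
        start=nw,
    )

    # per-eye supra-threshold run starts, for causal confirmation times
    def eye_runs(vel: np.ndarray, thr: float):
        mask = np.zeros(n, dtype=bool)
        with np.errstate(invalid="ignore"):
            mask[nw:] = np.abs(vel[nw:]) > thr
        return [
            (a, b) for a, b in _runs(mask) if b - a + 1 >= min_frames
        ]

    runs_per_eye = (
        eye_runs(vt.v_left, nt.eta_left),
        eye_runs(vt.v_right, nt.eta_right),
    )

    def confirm_frame(event: SaccadeEvent) -> int:
        """First frame index at which the event's onset is causally
        confirmed: every contributing eye's run must span the minimum frame
        count, and each velocity sample lags its frame by two frames."""
        ks = []
        for runs in runs_per_eye:
            inside = [
                a for a, b in runs if a <= event.i_end and b >= event.i_start
            ]
            if inside:
                ks.append(min(inside) + min_frames - 1)
        base = max(ks) if ks else event.i_start + min_frames - 1
        return base + 2

    slow: List[SlowPhaseEvent] = []
    decision_time: Optional[float] = None
    for prev, nxt in zip(saccades[:-1], saccades[1:]):
        g0, g1 = prev.i_end + 1, nxt.i_start
        if g1 - g0 < 2:
            continue
        ev = validate_slow_phase(
            frames.t[g0:g1],
            xl[g0:g1],
            xr[g0:g1],
            stimulus.direction,
            cfg,
        )
        if ev is None:
            continue
        slow.append(ev)
        if len(slow) == cfg.robust_count and decision_time is None:
            k = confirm_frame(nxt)
            if k < n and frames.t[k] - t0 <= timeout_ms + 1e-9:
                decision_time = float(frames.t[k])
    seen = decision_time is not None
    return DetectionResult(
        okn_present=seen,
        n_valid_slow_phases=len(slow),
        saccades=list(saccades),
        slow_phases=slow,
        decision_time_ms=decision_time if seen else t0 + timeout_ms,
    )


def replay_compare(
    trace: GazeTrace,
    stimulus: StimulusSpec,
    config: Optional[DetectorConfig] = None,
) -> dict:
    """Run both detection methods on the same recording.

    The live method sees the frame-rate decimation, the offline method the
    full-rate trace (with blink removal); the pair of decisions supports
    concordance analysis against labeled corpora.
    """
    from .offline_detector import analyze_trial_offline

    config = config or DetectorConfig()
    live = detect_live(trace, stimulus, config)
    offline = analyze_trial_offline(trace, stimulus, config)
    return {
        "live": live,
        "offline": offline,
        "live_decision": live.okn_present,
        "offline_decision": offline.okn_present,
        "concordant": live.okn_present == offline.okn_present,
    }
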