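"""Synthetic-data generation: labeled OKN and fixation gaze traces, virtual
psychometric observers, and the closed-loop experiment runner.

The optokinetic trace is the canonical saw-tooth: slow phases tracking the
stimulus drift at ``gain x stimulus velocity`` (gain defaults to 0.76, the
EOG-measured population value), interleaved with quick phases — smooth
sigmoid resets of the configured amplitude and duration against the drift.
The eye starts at the fixation center and the quick phase triggers once the
eye has drifted ``beating_field_offset_deg`` past center in the drift
direction, i.e. the oscillation's beating field is offset toward the
stimulus motion, so the first quick phase arrives a few hundred
milliseconds after onset, well clear of the noise-estimation window.

Sensor noise is band-limited: white Gaussian noise low-pass filtered with a
Gaussian kernel (``noise_correlation_ms``) and rescaled to the configured
positional SD, mimicking video-oculography noise whose power does not
extend to the Nyquist frequency.  Both eyes share the signal plus this
common noise and additionally carry independent disparity noise.  Blinks
are Poisson-placed track-lost runs (positions NaN, pupil 0).

Every generated trace carries its ground-truth label and event list in
``meta``; all detection-performance metrics in the tests are computed
against these labels.  All generators are seeded and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import DetectorConfig
from .csf_fit import CSFParams, fit_csf, logparabola
from .errors import ConfigError
from .gaze import GazeTrace
from .live_detector import detect_live
from .psychometric import (
    C_WEIBULL,
    OutcomeTable,
    PsychometricFit,
    PsychometricParams,
    fit_psychometric,
    weibull_psi,
)
from .quest_plus import DEFAULT_SLOPE_GRID, QuestPlus
from .stimulus_geometry import (
    DEFAULT_SF_SET,
    ExperimentPlan,
    StimulusSpec,
    contrast_ladder,
    plan_experiment,
)

__all__ = [
    "OKNGenParams",
    "VirtualObserver",
    "synth_okn_trace",
    "synth_fixation_trace",
    "observe_trial",
    "run_closed_loop",
    "ClosedLoopResult",
    "make_labeled_corpus",
]


@dataclass
class OKNGenParams:
    """Generator parameters for synthetic gaze traces."""

    gain: float = 0.76
    saccade_amplitude_deg: float = 2.0
    saccade_duration_ms: float = 30.0
    position_noise_sd_deg: float = 0.05
    noise_correlation_ms: float = 5.0
    blink_rate_hz: float = 0.1
    blink_duration_ms: float = 150.0
    binocular_disparity_noise_deg: float = 0.02
    onset_latency_ms: float = 200.0
    beating_field_offset_deg: float = 0.4
    fixation_drift_dps: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.gain <= 1.5):
            raise ConfigError("gain must be in (0, 1.5]")
        for name in (
            "position_noise_sd_deg",
            "blink_rate_hz",
            "blink_duration_ms",
            "binocular_disparity_noise_deg",
            "fixation_drift_dps",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


def _correlated_noise(
    rng: np.random.Generator, n: int, sd: float, corr_ms: float, rate_hz: float
) -> np.ndarray:
    """Band-limited Gaussian noise with the requested sample SD."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sigma_samples = corr_ms * rate_hz / 1000.0
    if sigma_samples > 0.3:
        out = gaussian_filter1d(white, sigma_samples, mode="nearest")
        s = out.std()
        if s > 0:
            out = out / s
    else:
        out = white
    return out * sd


def _sigmoid_step(u: np.ndarray, duration: float) -> np.ndarray:
    """Normalized smooth step on [0, duration] rising 0 -> 1 (logistic with
    95% of the excursion inside the nominal duration)."""
    k = 2.0 * math.log(19.0) / duration
    mid = duration / 2.0
    lo = 1.0 / (1.0 + math.exp(k * mid))
    hi = 1.0 / (1.0 + math.exp(-k * mid))
    return (1.0 / (1.0 + np.exp(-k * (u - mid))) - lo) / (hi - lo)


def _insert_blinks(
    rng: np.random.Generator,
    t: np.ndarray,
    gen: OKNGenParams,
    arrays: List[np.ndarray],
    pupils: List[np.ndarray],
) -> List[Tuple[float, float]]:
    duration_s = (t[-1] - t[0] + (t[1] - t[0])) / 1000.0 if t.size > 1 else 0.0
    n_blinks = rng.poisson(gen.blink_rate_hz * duration_s)
    intervals: List[Tuple[float, float]] = []
    for _ in range(n_blinks):
        b0 = t[0] + rng.uniform(0.0, duration_s * 1000.0)
        b1 = b0 + gen.blink_duration_ms
        mask = (t >= b0) & (t < b1)
        for a in arrays:
            a[mask] = np.nan
        for p in pupils:
            p[mask] = 0.0
        intervals.append((float(b0), float(b1)))
    return sorted(intervals)


def _assemble_trace(
    rng: np.random.Generator,
    t: np.ndarray,
    x_signal: np.ndarray,
    gen: OKNGenParams,
    rate_hz: float,
    meta: dict,
    with_blinks: bool = True,
) -> GazeTrace:
    n = t.size
    common = _correlated_noise(
        rng, n, gen.position_noise_sd_deg, gen.noise_correlation_ms, rate_hz
    )
    disp_l = _correlated_noise(
        rng, n, gen.binocular_disparity_noise_deg, gen.noise_correlation_ms, rate_hz
    )
    disp_r = _correlated_noise(
        rng, n, gen.binocular_disparity_noise_deg, gen.noise_correlation_ms, rate_hz
    )
    x_l = x_signal + common + disp_l
    x_r = x_signal + common + disp_r
    y_l = _correlated_noise(
        rng, n, gen.position_noise_sd_deg, gen.noise_correlation_ms, rate_hz
    )
    y_r = _correlated_noise(
        rng, n, gen.position_noise_sd_deg, gen.noise_correlation_ms, rate_hz
    )
    p_l = 1000.0 + rng.standard_normal(n) * 5.0
    p_r = 1000.0 + rng.standard_normal(n) * 5.0
    blink_intervals: List[Tuple[float, float]] = []
    if with_blinks and gen.blink_rate_hz > 0:
        blink_intervals = _insert_blinks(
            rng, t, gen, [x_l, x_r, y_l, y_r], [p_l, p_r]
        )
    meta = dict(meta)
    meta["blink_intervals"] = blink_intervals
    return GazeTrace(
        t=t,
        x_left=x_l,
        y_left=y_l,
        x_right=x_r,
        y_right=y_r,
        pupil_left=p_l,
        pupil_right=p_r,
        rate_hz=rate_hz,
        meta=meta,
    )


def synth_okn_trace(
    stimulus: StimulusSpec,
    gen: Optional[OKNGenParams] = None,
    duration_s: float = 4.0,
    rate_hz: float = 1000.0,
    seed: Optional[int] = None,
) -> GazeTrace:
    """Saw-tooth OKN trace with ground-truth labels (OKN present).

    Slow phases drift at ``gain * velocity`` with the stimulus; quick
    phases are smooth sigmoid resets against it.  ``meta`` carries the
    ground-truth quick-phase intervals, the slow-phase velocity, and the
    label ``"okn"``.
    """
    gen = gen or OKNGenParams()
    if duration_s <= 0:
        raise ConfigError("duration must be positive")
    rng = np.random.default_rng(seed if seed is not None else gen.seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) * (1000.0 / rate_hz)
    d = stimulus.direction
    sp_v = gen.gain * stimulus.velocity_dps * d       # deg/s, signed
    amp = gen.saccade_amplitude_deg
    sac_ms = gen.saccade_duration_ms
    trigger = gen.beating_field_offset_deg

    x = np.empty(n)
    qp_intervals: List[Tuple[float, float]] = []
    sp_segments: List[Tuple[float, float]] = []
    # reflexive tracking starts after the OKN onset latency; the eye holds
    # fixation until then, which also keeps the live method's short
    # noise-estimation window representative of tracker noise
    i_lat = min(n, int(round(gen.onset_latency_ms * rate_hz / 1000.0)))
    x[:i_lat] = 0.0
    pos = 0.0
    t_ms = t[i_lat] if i_lat < n else 0.0
    i = i_lat
    while i < n:
        # slow phase until the eye reaches the trigger eccentricity
        dist = trigger - d * pos                      # deg still to drift
        sp_dur_ms = max(dist, 0.0) / abs(sp_v) * 1000.0
        j = min(n, i + int(round(sp_dur_ms * rate_hz / 1000.0)))
        if j > i:
            seg_t = t[i:j] - t_ms
            x[i:j] = pos + sp_v * seg_t / 1000.0
            sp_segments.append((float(t[i]), float(t[min(j, n) - 1])))
        if j >= n:
            break
        pos = pos + sp_v * (t[j] - t_ms) / 1000.0
        t_ms = t[j]
        # quick phase: smooth reset of `amp` against the drift
        k = min(n, j + int(round(sac_ms * rate_hz / 1000.0)))
        seg_t = t[j:k] - t_ms
        x[j:k] = pos - d * amp * _sigmoid_step(seg_t, sac_ms)
        qp_intervals.append((float(t[j]), float(t_ms + sac_ms)))
        if k >= n:
            break
        pos = pos - d * amp
        i = k
        t_ms = t[k]  # saccade end realigned to the sample grid

    meta = {
        "label": "okn",
        "stimulus_direction": d,
        "sp_velocity_dps": sp_v,
        "qp_intervals": qp_intervals,
        "sp_segments": sp_segments,
        "gain": gen.gain,
    }
    return _assemble_trace(rng, t, x, gen, rate_hz, meta)


def synth_fixation_trace(
    gen: Optional[OKNGenParams] = None,
    duration_s: float = 4.0,
    rate_hz: float = 1000.0,
    drift_dps: Optional[float] = None,
    seed: Optional[int] = None,
) -> GazeTrace:
    """Stationary fixation trace with optional sub-threshold drift
    (OKN absent; the negative class of the detection evaluation)."""
    gen = gen or OKNGenParams()
    if duration_s <= 0:
        raise ConfigError("duration must be positive")
    rng = np.random.default_rng(seed if seed is not None else gen.seed)
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) * (1000.0 / rate_hz)
    drift = gen.fixation_drift_dps if drift_dps is None else drift_dps
    direction = rng.choice([-1.0, 1.0])
    x = direction * drift * t / 1000.0
    meta = {"label": "fixation", "drift_dps": float(direction * drift)}
    return _assemble_trace(rng, t, x, gen, rate_hz, meta)


# ---------------------------------------------------------------------------
# virtual observers


@dataclass
class VirtualObserver:
    """Ground-truth psychometric observer: per spatial frequency, the true
    Weibull parameters governing the per-trial OKN probability."""

    true_params: Dict[float, PsychometricParams]
    gen: OKNGenParams = field(default_factory=OKNGenParams)
    label: str = "observer"

    def p_seen(self, sf_cpd: float, contrast: float) -> float:
        params = self.true_params[sf_cpd]
        return float(weibull_psi(contrast, params))

    @classmethod
    def from_csf(
        cls,
        csf: CSFParams,
        sf_set: Sequence[float] = DEFAULT_SF_SET,
        slope: float = 3.0,
        gen: Optional[OKNGenParams] = None,
        label: str = "observer",
        high_sf_attenuation_per_cpd: float = 0.0,
    ) -> "VirtualObserver":
        """Observer whose thresholds follow a log-parabola CSF.

        ``high_sf_attenuation_per_cpd`` models optical defocus as a
        low-pass modulation-transfer loss: sensitivity is reduced by that
        many log10 units per cpd, hitting high spatial frequencies hardest
        (the canonical blur signature).
        """
        params: Dict[float, PsychometricParams] = {}
        for sf in sf_set:
            log_cs = logparabola(sf, csf) - high_sf_attenuation_per_cpd * sf
            ct = 10.0 ** (-log_cs)
            params[float(sf)] = PsychometricParams(
                m=math.log(ct), w=C_WEIBULL / slope
            )
        return cls(
            true_params=params,
            gen=gen or OKNGenParams(),
            label=label,
        )


def default_defocus_observers(
    csf: Optional[CSFParams] = None,
    sf_set: Sequence[float] = DEFAULT_SF_SET,
    slope: float = 3.0,
    gen: Optional[OKNGenParams] = None,
) -> Dict[str, VirtualObserver]:
    """Observers for the in-focus condition and three defocus steps.

    Defocus raises thresholds preferentially at high spatial frequency via
    an increasing high-SF attenuation, reproducing the qualitative pattern
    of blur on the contrast-sensitivity function.
    """
    csf = csf or CSFParams(gamma_max=150.0, sf_max=1.5, beta=2.2)
    attenuation = {"0.0D": 0.0, "+1.5D": 0.06, "+2.0D": 0.10, "+2.5D": 0.14}
    return {
        cond: VirtualObserver.from_csf(
            csf,
            sf_set=sf_set,
            slope=slope,
            gen=gen,
            label=cond,
            high_sf_attenuation_per_cpd=a,
        )
        for cond, a in attenuation.items()
    }


def observe_trial(
    observer: VirtualObserver,
    stimulus: StimulusSpec,
    seed: int,
    duration_s: Optional[float] = None,
    rate_hz: float = 1000.0,
) -> Tuple[GazeTrace, bool]:
    """Simulate one presentation: OKN occurs with the observer's Weibull
    probability at the stimulus contrast; the emitted trace is a saw-tooth
    or a fixation trace accordingly, with the ground-truth label returned.
    """
    rng = np.random.default_rng(seed)
    p = observer.p_seen(stimulus.sf_cpd, stimulus.contrast)
    present = bool(rng.random() < p)
    child = int(rng.integers(2**31))
    duration = duration_s if duration_s is not None else stimulus.duration_max_s
    if present:
        trace = synth_okn_trace(
            stimulus, observer.gen, duration_s=duration, rate_hz=rate_hz,
            seed=child,
        )
    else:
        trace = synth_fixation_trace(
            observer.gen, duration_s=duration, rate_hz=rate_hz, seed=child
        )
    trace.meta["okn_present"] = present
    return trace, present


def make_labeled_corpus(
    n_positive: int,
    n_negative: int,
    gen: Optional[OKNGenParams] = None,
    stimulus: Optional[StimulusSpec] = None,
    duration_s: float = 4.0,
    rate_hz: float = 1000.0,
    seed: int = 0,
) -> List[GazeTrace]:
    """Labeled evaluation corpus: OKN traces (alternating drift direction)
    plus fixation traces, each carrying its ground-truth label in meta."""
    gen = gen or OKNGenParams()
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_positive + n_negative) % (2**31)
    corpus: List[GazeTrace] = []
    for i in range(n_positive):
        stim = stimulus or StimulusSpec(
            sf_cpd=1.5, contrast=0.33, direction=1 if i % 2 == 0 else -1
        )
        corpus.append(
            synth_okn_trace(
                stim, gen, duration_s=duration_s, rate_hz=rate_hz,
                seed=int(seeds[i]),
            )
        )
        corpus[-1].meta["stimulus"] = stim
    for i in range(n_negative):
        tr = synth_fixation_trace(
            gen, duration_s=duration_s, rate_hz=rate_hz,
            seed=int(seeds[n_positive + i]),
        )
        tr.meta["stimulus"] = stimulus or StimulusSpec(
            sf_cpd=1.5, contrast=0.33, direction=1 if i % 2 == 0 else -1
        )
        corpus.append(tr)
    return corpus


# ---------------------------------------------------------------------------
# closed loop


@dataclass
class SFResult:
    """Per-spatial-frequency outcome of a closed-loop run."""

    sf_cpd: float
    table: OutcomeTable
    fit: PsychometricFit
    quest_log: dict
    true_m: Optional[float] = None


@dataclass
class ClosedLoopResult:
    """Full closed-loop session: per-SF staircases, fits, and the CSF."""

    per_sf: Dict[float, SFResult]
    csf: Optional[CSFParams]
    audit: pd.DataFrame

    @property
    def cs_values(self) -> Dict[float, float]:
        return {sf: r.fit.params.cs for sf, r in self.per_sf.items()}


def run_closed_loop(
    observer: VirtualObserver,
    plan: Optional[ExperimentPlan] = None,
    config: Optional[DetectorConfig] = None,
    seed: int = 0,
    ladder: Optional[np.ndarray] = None,
    slope_grid: Optional[np.ndarray] = None,
    detector: str = "live",
    rate_hz: float = 1000.0,
) -> ClosedLoopResult:
    """Run the adaptive experiment end to end against a virtual observer.

    For each spatial frequency: 64 trials (by default) of QUEST+ contrast
    selection -> simulated presentation -> live OKN detection on the
    frame-rate decimated trace -> posterior update.  The per-SF outcome
    table is then fitted with the Weibull psychometric function and the
    resulting sensitivities with the log-parabola CSF.  ``detector`` may be
    ``"live"``, ``"offline"``, or ``"oracle"`` (the ground-truth label,
    bypassing gaze analysis — the perfect-detection reference).
    """
    from .offline_detector import analyze_trial_offline

    plan = plan or ExperimentPlan()
    config = config or DetectorConfig()
    if ladder is None:
        ladder = contrast_ladder()
    if slope_grid is None:
        slope_grid = DEFAULT_SLOPE_GRID
    if detector not in ("live", "offline", "oracle"):
        raise ConfigError(f"unknown detector {detector!r}")

    schedule = plan_experiment(plan, seed)
    ss = np.random.SeedSequence([seed, 1])
    trial_seeds = iter(ss.generate_state(len(schedule)) % (2**31))

    step = float(np.median(np.diff(np.log(ladder))))
    m_bounds = (float(np.log(ladder[0]) - step), float(np.log(ladder[-1]) + step))

    per_sf: Dict[float, SFResult] = {}
    rows = []
    # single-condition schedule: group by SF in scheduled order
    sf_order = list(dict.fromkeys(s.sf_cpd for s in schedule))
    for sf in sf_order:
        slots = [s for s in schedule if s.sf_cpd == sf]
        quest = QuestPlus(ladder, slope_grid)
        trials = []
        for slot in slots:
            contrast = quest.next_contrast()
            stim = StimulusSpec(
                sf_cpd=sf,
                contrast=contrast,
                velocity_dps=plan.velocity_dps,
                direction=slot.direction,
                duration_max_s=plan.timeout_s,
            )
            tseed = int(next(trial_seeds))
            trace, present = observe_trial(
                observer, stim, seed=tseed, rate_hz=rate_hz
            )
            if detector == "oracle":
                seen = present
                decision_time = trace.t[-1]
            elif detector == "offline":
                res = analyze_trial_offline(trace, stim, config)
                seen, decision_time = res.okn_present, res.decision_time_ms
            else:
                res = detect_live(trace, stim, config)
                seen, decision_time = res.okn_present, res.decision_time_ms
            quest.update(contrast, seen)
            trials.append((contrast, seen))
            rows.append(
                {
                    "sf_cpd": sf,
                    "trial": slot.index,
                    "direction": slot.direction,
                    "contrast": contrast,
                    "okn_present_truth": present,
                    "decision": seen,
                    "decision_time_ms": decision_time,
                }
            )
        table = OutcomeTable.from_trials(trials)
        fit = fit_psychometric(table, m_bounds=m_bounds)
        per_sf[sf] = SFResult(
            sf_cpd=sf,
            table=table,
            fit=fit,
            quest_log=quest.to_log(),
            true_m=(
                observer.true_params[sf].m
                if sf in observer.true_params
                else None
            ),
        )

    csf: Optional[CSFParams] = None
    if len(per_sf) >= 4:
        sfs = sorted(per_sf)
        csf = fit_csf(sfs, [per_sf[s].fit.params.cs for s in sfs])
    return ClosedLoopResult(
        per_sf=per_sf, csf=csf, audit=pd.DataFrame(rows)
    )
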