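# Methods

This note documents the models implemented in `oknlab`, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical choices a maintainer should know about.

## Quick-phase detection

Horizontal gaze position (degrees of visual angle, rightward positive) is
differentiated with the five-point moving-window kernel

    v_n = (x_{n+2} + x_{n+1} − x_{n−1} − x_{n−2}) / (6 Δt),

which is exact for affine signals and attenuates high-frequency sensor
noise. Only the horizontal component is analyzed. The per-eye noise scale
is the centered median estimator

    σ = sqrt( median( (v − median v)² ) ),

and the detection threshold is η = λσ with λ = 7. The centered form is
used (rather than `median(v²) − (median v)²`) because it is exactly
invariant under adding a constant velocity and exactly homogeneous under
scaling, and it cannot collapse to zero when a drift offset occupies part
of the estimation window; the two forms coincide for zero-median windows.
With exactly constant velocity input σ = 0 and η = 0, at which point the
threshold test degenerates — velocity-threshold detection inherently
requires a nonzero noise floor, which is why the test fixtures' "clean"
traces carry a tiny (0.005°) sensor noise rather than none.

A saccade (OKN quick phase) is a maximal run of samples with |v| > η,
lasting at least `min_saccade_duration_ms` (6 ms at 1000 Hz; two frames at
120 Hz). With the binocular criterion (default on), a monocular run
survives only if it overlaps a run of the other eye by at least one
sample, and the merged (union) interval is reported. Offline, events
closer than 50 ms are merged — overshoot protection. Runs touching the
trace boundary are kept if they meet the minimum duration; masked (NaN)
samples never start a run, and the velocity of a sample whose own position
is missing is masked even though the kernel skips the center sample.

## Slow-phase validation and the robust-OKN rule

Every inter-saccadic gap is a candidate slow phase. The gap is shrunk by
`trim_ms` (17 ms ≈ two refresh periods) at both ends to discard saccadic
overshoot, the position is smoothed with a centered 5-sample moving
average, and the mean velocity is the endpoint displacement of the
smoothed signal over its duration, per eye, averaged over eyes with usable
data (an eye whose smoothed segment has fewer than two finite samples is
dropped; a per-sample-mean estimator is available via
`sp_velocity_estimator="mean_sample"` — on clean data both coincide). The
slow phase is valid iff its velocity sign matches the stimulus drift
direction and its magnitude reaches `sp_velocity_threshold_dps`.

**The slow-phase velocity threshold (0.5 °/s default) has no published
reference value.** It was set to a conservative fraction of the 2.3 °/s
stimulus (expected slow-phase speed ≈ gain × 2.3 ≈ 1.7 °/s) and is exposed
in `DetectorConfig`; it should be revisited for other stimulus speeds, and
a contrast-dependent threshold would be the natural refinement since OKN
gain drops at low contrast.

A trial is *seen* once `robust_count = 2` valid slow phases have been
found. Counting "two OKN events" as two validated slow phases or as two
quick-phase/slow-phase pairs is the same number under this bracketed
definition (every validated slow phase is closed by a quick phase), so a
single implementation covers both readings.

## Live vs offline analysis

The live detector consumes one representative gaze sample per 120 Hz
display frame (latest-sample decimation; `live_full_rate=True` analyzes
the tracker rate instead). The first 34 frames (≈283 ms) are used only to
fix η; scanning starts afterwards. Analysis is strictly causal: the
five-point kernel makes the velocity of frame *j* available two frames
later, so the detection-latency floor is ≈17 ms, and the *seen* decision
is emitted at the exact frame where the closing saccade's onset is
confirmed (each contributing eye's run reaching the minimum frame count,
plus the two-frame lookahead). Without a decision the trial ends *not
seen* at the 4 s timeout. Live mode deliberately has **no blink
handling** — non-finite samples just produce masked velocities — mirroring
the reference protocol's limitation so that live/offline discordances are
reproducible. A blink-dominated noise window means no threshold can be
fixed; the trial then cannot detect anything and times out (both modes).

The offline detector re-analyzes the full-rate recording: blink runs
(pupil 0/NaN) dilated by a 50 ms buffer are masked, saccades use the 50 ms
minimum separation, and the same noise window (first ≈283 ms) is used for
comparability with the live method. Offline scans the whole trace (it is
post-hoc), live only after the noise window. `replay_compare` runs both on
the same recording; a batch replay of the live semantics
(`detect_live`) is equivalence-tested frame-for-frame against the
streaming `LiveDetector`.

## Adaptive staircase

QUEST+ maintains a posterior over 39 candidate thresholds (the displayable
contrast ladder, log-spaced 0.0003–0.66) × 11 slopes (0.5–5.5 step 0.5),
with zero guess and lapse rates. The prior is uniform by default (the
protocol's prior is unspecified). The next contrast minimizes the expected
posterior entropy of the full joint over the two outcomes, restricted to
the ladder; ties break toward the lower contrast (prefer the harder
stimulus; deterministic). Note the consequence tested in the suite: with
the threshold known and only the slope uncertain, the optimum sits a few
steps up the flank — at the threshold itself every slope predicts
P(seen) = 0.5, which is uninformative about slope. The staircase object is
fully deterministic; all randomness lives in the simulated observers.

## Psychometric and CSF fits

The cumulative Weibull is parametrized by the log-threshold *m* and width
*w* (natural logs), with c = log(−log 0.05) − log(−log 0.95), so that the
0.05–0.95 quantile span equals *w* exactly, Ψ(e^m) = 0.5, CT = e^m,
CS = 1/CT, slope s = c/w. Contrast is a Michelson fraction in (0, 1]
internally; percent is display formatting. Fitting is direct
maximum-likelihood (product-binomial) via a coarse grid plus Nelder-Mead
refinement on (m, log w), with m bounded to the tested range ± one level
spacing; an all-seen/none-seen table returns a boundary estimate flagged
`converged=False` with a warning. A dense-grid likelihood oracle
cross-checks the optimizer in the tests.

The CSF is the pure log-parabola (no low-SF truncation):
log₁₀ CS(SF) = log₁₀ γmax − log₁₀2 · ((log₁₀ SF − log₁₀ SFmax)/(β/2))².
The left side is log₁₀ sensitivity; fitting and R² are computed in that
space, where threshold-estimate noise is approximately homogeneous. β is a
bandwidth in log₁₀-cpd units exactly as written (no octave conversion).
Fitting is bounded least squares initialized at the empirical peak, with
SFmax confined to [min SF/2, max SF×2]; identical-CS input yields R² = 0
by the SS_tot = 0 convention, with a warning.

## Simulator

`synth_okn_trace` builds the canonical saw-tooth: after a 200 ms onset
latency (the eye holds fixation; reflexive tracking in humans starts a few
hundred milliseconds after motion onset, which also keeps the live
method's short noise window representative of tracker noise), slow phases
drift at gain × stimulus velocity (gain default 0.76, the EOG-measured
population value) until the eye is 0.4° past center in the drift direction
(the beating field is offset toward stimulus motion), then a smooth
logistic quick phase of 2.0° amplitude and 30 ms duration resets it. With
the 2.3 °/s stimulus this yields a first quick phase ≈0.43 s after onset
and four quick phases per 4 s trial. Sensor noise is band-limited:
Gaussian-filtered white noise (5 ms correlation) rescaled to 0.05° SD —
video-oculography noise is not white out to Nyquist, and white 0.05° noise
at 1000 Hz would imply ≈17 °/s velocity noise, swamping every quick phase.
Both eyes share the signal and the common noise, plus independent 0.02°
disparity noise. Blinks are Poisson track-lost runs (0.1 Hz, 150 ms;
subjects in the reference protocol are asked to blink between trials, so
in-trial blinks are rare). Fixation traces drift at 0.1 °/s (below the
slow-phase threshold). Every trace carries its ground-truth label, event
intervals, and generator parameters in `meta`; detection metrics in the
tests are always computed against these labels.

`VirtualObserver` is per-trial Bernoulli: OKN is present for the whole
trial with probability Ψ(contrast; true m, w). Defocus observers model
blur as a low-pass transfer loss — sensitivity reduced by 0.06/0.10/0.14
log₁₀ units per cpd for +1.5/+2.0/+2.5 D — raising thresholds
preferentially at high spatial frequency. The default in-focus observer
has a log-parabola CSF (γmax = 150, SFmax = 1.5 cpd, β = 2.2) and Weibull
slope 3.0 (mid-range of the staircase's slope grid).

What the simulator does **not** emulate: within-trial OKN onset dynamics
conditioned on contrast (gain is contrast-independent), ballistic saccade
kinematics and the main sequence, pupil dynamics, vergence, head motion,
calibration drift, and look-OKN attention effects. Passing the detection
criteria on this corpus therefore demonstrates the pipeline's correctness
and its behavior under realistic noise/blink statistics, not human-data
detection rates.

## Problem sizes and determinism

Every stochastic component takes an explicit seed; identical seeds give
byte-identical traces and identical decisions. The test suite's corpus
evaluation uses 200 labeled 4 s trials; closed-loop recovery uses 20 seeded
sessions × 6 spatial frequencies × 64 trials, recovering log-thresholds
with median absolute error below half a ladder step (0.101 natural-log
units). These sizes keep the full suite around a minute on one core while
leaving the binomial error of the measured rates well below the margins
being asserted.

## Known limitations

- The slow-phase velocity threshold is a free parameter (see above).
- The live method inherits the reference protocol's weaknesses by design:
  no blink handling, and a noise estimate from a short window.
- The psychometric fit returns point estimates only (no credible
  intervals); guess/lapse rates are fixed at zero as in the protocol.
- The log-parabola has no truncation term; strongly plateaued low-SF limbs
  would be misfit.
- Pixel-to-degree conversion uses small-extent geometry per axis
  (`ScreenGeometry.px_to_deg`); gaze is assumed already calibrated in
  degrees.
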