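import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oknlab import GazeTrace
from oknlab.errors import InsufficientDataError, NoiseEstimationError
from oknlab.velocity_engine import (
    NoiseThreshold,
    VelocityTrace,
    compute_velocity,
    detect_saccades,
    mask_blinks,
    noise_threshold,
)
from oracles import (
    blink_dilation_oracle,
    median_sigma_oracle,
    saccade_intervals_oracle,
)


def make_trace(x, rate=1000.0, pupil=None):
    n = len(x)
    x = np.asarray(x, dtype=float)
    pupil = np.full(n, 800.0) if pupil is None else np.asarray(pupil, float)
    return GazeTrace(
        t=np.arange(n) * 1000.0 / rate,
        x_left=x,
        y_left=np.zeros(n),
        x_right=x.copy(),
        y_right=np.zeros(n),
        pupil_left=pupil,
        pupil_right=pupil.copy(),
        rate_hz=rate,
    )


# -- velocity kernel ----------------------------------------------------


def test_velocity_constant_position_is_zero():
    vt = compute_velocity(make_trace(np.full(50, 3.0)))
    assert np.all(np.isnan(vt.v_left[:2])) and np.all(np.isnan(vt.v_left[-2:]))
    np.testing.assert_allclose(vt.v_left[2:-2], 0.0, atol=1e-12)


@pytest.mark.parametrize("slope_dps", [1.0, -2.3, 17.5])
def test_velocity_exact_on_linear_ramp(slope_dps):
    t_s = np.arange(100) / 1000.0
    vt = compute_velocity(make_trace(slope_dps * t_s))
    np.testing.assert_allclose(vt.v_left[2:-2], slope_dps, rtol=1e-9)


def test_velocity_matches_analytic_derivative_of_sinusoid():
    f = 1.0
    t_s = np.arange(1000) / 1000.0
    vt = compute_velocity(make_trace(np.sin(2 * np.pi * f * t_s)))
    analytic = 2 * np.pi * f * np.cos(2 * np.pi * f * t_s)
    err = np.abs(vt.v_left[2:-2] - analytic[2:-2])
    # five-point kernel error for a sinusoid is O((omega*dt)^2) relative
    assert err.max() < 1e-4 * 2 * np.pi * f


def test_velocity_insufficient_samples():
    with pytest.raises(InsufficientDataError):
        compute_velocity(make_trace([0.0, 1.0, 2.0, 3.0]))


def test_velocity_nan_propagates_from_masked_positions():
    x = np.zeros(30)
    x[10] = np.nan
    vt = compute_velocity(make_trace(x))
    assert np.all(np.isnan(vt.v_left[8:13]))
    assert np.isfinite(vt.v_left[7]) and np.isfinite(vt.v_left[13])


# -- noise threshold ----------------------------------------------------


def _vt(v, rate=1000.0):
    v = np.asarray(v, dtype=float)
    return VelocityTrace(
        t=np.arange(v.size) * 1000.0 / rate,
        v_left=v,
        v_right=v.copy(),
        rate_hz=rate,
    )


def test_noise_sigma_zero_for_constant_velocity():
    nt = noise_threshold(_vt(np.full(20, 4.2)), lambda_noise=7.0)
    assert nt.sigma_left == 0.0
    assert nt.eta_left == 0.0


def test_noise_sigma_matches_bruteforce_oracle():
    v = np.array([0.3, -1.2, 4.0, 0.1, -0.5, 2.2, -3.3, 0.8, 1.1, -0.2, 0.0])
    nt = noise_threshold(_vt(v))
    assert nt.sigma_left == pytest.approx(median_sigma_oracle(v), abs=1e-12)
    assert nt.eta_left == pytest.approx(7.0 * nt.sigma_left)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    st.lists(st.floats(-50, 50), min_size=5, max_size=60),
    st.floats(0.1, 10),
    st.floats(-20, 20),
)
def test_noise_sigma_shift_invariant_and_homogeneous(vals, k, shift):
    v = np.asarray(vals)
    s0 = noise_threshold(_vt(v)).sigma_left
    s_shift = noise_threshold(_vt(v + shift)).sigma_left
    s_scale = noise_threshold(_vt(v * k)).sigma_left
    assert s_shift == pytest.approx(s0, abs=1e-6 * max(1.0, abs(shift)))
    assert s_scale == pytest.approx(abs(k) * s0, rel=1e-9, abs=1e-9)


def test_noise_all_nan_window_raises():
    with pytest.raises(NoiseEstimationError):
        noise_threshold(_vt(np.full(20, np.nan)))


def test_noise_window_restricted_to_range():
    v = np.concatenate([np.zeros(20), np.full(20, 100.0)])
    nt = noise_threshold(_vt(v), window=(0, 20))
    assert nt.sigma_left == 0.0


# -- saccade detection --------------------------------------------------


def _binoc_vt(vl, vr, rate=1000.0):
    vl, vr = np.asarray(vl, float), np.asarray(vr, float)
    return VelocityTrace(
        t=np.arange(vl.size) * 1000.0 / rate, v_left=vl, v_right=vr,
        rate_hz=rate,
    )


def _eta(el, er, lam=1.0):
    return NoiseThreshold(sigma_left=el / lam, sigma_right=er / lam,
                          lambda_noise=lam)


def test_no_events_below_threshold():
    vt = _binoc_vt(np.zeros(100), np.zeros(100))
    assert detect_saccades(vt, _eta(5.0, 5.0)) == []


def test_two_close_runs_merged_by_min_separation():
    v = np.zeros(200)
    v[50:60] = 40.0
    v[90:100] = 40.0  # 30 ms gap at 1000 Hz
    vt = _binoc_vt(v, v)
    events = detect_saccades(vt, _eta(5.0, 5.0), min_separation_ms=50.0)
    assert len(events) == 1
    assert (events[0].i_start, events[0].i_end) == (50, 99)
    events2 = detect_saccades(vt, _eta(5.0, 5.0), min_separation_ms=0.0)
    assert len(events2) == 2


def test_monocular_run_dropped_without_overlap():
    vl = np.zeros(100)
    vl[40:50] = 30.0
    vr = np.zeros(100)
    vt = _binoc_vt(vl, vr)
    assert detect_saccades(vt, _eta(5.0, 5.0), binocular_required=True) == []
    mono = detect_saccades(vt, _eta(5.0, 5.0), binocular_required=False)
    assert len(mono) == 1 and not mono[0].binocular


def test_overlapping_runs_reported_as_union():
    vl = np.zeros(100)
    vl[40:50] = 30.0
    vr = np.zeros(100)
    vr[46:58] = -30.0
    vt = _binoc_vt(vl, vr)
    ev = detect_saccades(vt, _eta(5.0, 5.0))
    assert len(ev) == 1
    assert (ev[0].i_start, ev[0].i_end) == (40, 57)
    assert ev[0].binocular


@pytest.mark.parametrize("seed", range(60))
def test_saccade_detection_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(30, 500))
    rate = float(rng.choice([120.0, 500.0, 1000.0]))
    vl = rng.normal(0, 1, n)
    vr = rng.normal(0, 1, n)
    for v in (vl, vr):  # plant a few strong runs
        for _ in range(rng.integers(0, 5)):
            a = int(rng.integers(0, n - 5))
            L = int(rng.integers(1, 15))
            v[a : a + L] += rng.choice([-1, 1]) * rng.uniform(5, 30)
    if rng.random() < 0.3:
        vl[rng.integers(0, n, size=max(1, n // 20))] = np.nan
    vt = _binoc_vt(vl, vr, rate)
    eta = _eta(rng.uniform(1, 6), rng.uniform(1, 6))
    min_dur = float(rng.choice([0.0, 6.0, 2000.0 / rate]))
    min_sep = float(rng.choice([0.0, 50.0]))
    binoc = bool(rng.random() < 0.7)
    start = int(rng.integers(0, n // 3))
    events = detect_saccades(
        vt, eta, min_duration_ms=min_dur, min_separation_ms=min_sep,
        binocular_required=binoc, start=start,
    )
    expected = saccade_intervals_oracle(
        vt.t, vl, vr, eta.eta_left, eta.eta_right, min_dur, min_sep, binoc,
        rate, start=start,
    )
    assert [(e.i_start, e.i_end) for e in events] == expected
    # structural invariants: sorted, disjoint after merging
    for a, b in zip(events[:-1], events[1:]):
        assert a.i_end < b.i_start
        assert b.t_start - a.t_end >= min_sep


# -- blink masking ------------------------------------------------------


def test_mask_blinks_no_blinks_is_identity():
    trace = make_trace(np.zeros(100))
    out = mask_blinks(trace, 50.0)
    assert out.equals(trace)


def test_mask_blinks_dilates_by_buffer():
    pupil = np.full(1000, 800.0)
    pupil[500:600] = 0.0  # blink over t=[500, 600)
    trace = make_trace(np.zeros(1000), pupil=pupil)
    out = mask_blinks(trace, 50.0)
    lost = ~np.isfinite(out.x_left)
    assert lost[450] and lost[649]
    assert not lost[449] and not lost[650]


@pytest.mark.parametrize("seed", range(50))
def test_mask_blinks_matches_dilation_oracle(seed):
    rng = np.random.default_rng(seed + 1000)
    n = int(rng.integers(20, 400))
    rate = float(rng.choice([120.0, 1000.0]))
    pupil = np.full(n, 800.0)
    for _ in range(rng.integers(0, 4)):
        a = int(rng.integers(0, n))
        pupil[a : a + int(rng.integers(1, 30))] = 0.0
    buffer_ms = float(rng.choice([0.0, 10.0, 50.0]))
    trace = make_trace(rng.normal(size=n), rate=rate, pupil=pupil)
    out = mask_blinks(trace, buffer_ms)
    expected = blink_dilation_oracle(trace.t, pupil <= 0, buffer_ms)
    np.testing.assert_array_equal(~np.isfinite(out.x_left), expected)
    np.testing.assert_array_equal(out.pupil_left[np.array(expected)], 0.0)
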