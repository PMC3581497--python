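"""Synthetic oculography-session generator with embedded ground truth.

Generates multichannel raw records with the statistical structure the
analysis pipeline assumes: slow phases that follow the stimulus with a
configurable gain and phase, resetting fast phases triggered when the eye
grows eccentric, post-saccadic exponential glissades, behavioral arrests
(the eye decelerating to an eccentric hold during constant-velocity
stimulation), signal dropouts, a constant vertical drift bias, and a linear
within-session habituation ramp of gain. The generated angle trajectories
are pushed through the forward camera projection so that the calibration
stage can be tested end to end, and the generating parameters are embedded
in the record for recovery tests.

Sign conventions
----------------
Positive roll-axis planetarium velocity is upward motion with respect to the
recorded eye; positive vertical eye position is elevation above
earth-horizontal; a compensatory response has positive gain (the eye
counter-rotates against the turntable, or follows the planetarium).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .calibration import project_angles
from .stimuli import StimulusSpec

__all__ = [
    "SimTruth",
    "RawRecord",
    "simulate_sinusoidal_record",
    "simulate_step_record",
    "simulate_stationary_record",
    "simulate_calibration_sweep",
]

#: Acquisition sampling rate, samples/s.
DEFAULT_SAMPLE_RATE = 500.0
#: Video-oculography camera frame rate, Hz (optional quantization stage).
VIDEO_RATE = 120.0

_FAST_PHASE_DURATION = 0.020   # s
_ARREST_TAU = 0.30             # s, deceleration into an arrest
_REFRACTORY = 0.050            # s after a fast phase before re-triggering


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth parameters of one simulated record.

    Attributes
    ----------
    gain : float or mapping
        Slow-phase gain. For step records, may be a mapping from signed
        stimulus speed (deg/s) to gain; missing speeds use the nearest key.
    gain_up, gain_down : float, optional
        Directionally split gains for the upward/downward hemicycles of a
        sinusoidal stimulus (override ``gain`` when both are given).
    phase_deg : float
        Response phase in degrees, positive = eye leads the stimulus.
    drift_bias : float
        Constant vertical eye drift in deg/s, superimposed on the vertical
        response channel (roll and stationary records).
    resting_horizontal, resting_vertical : float
        Baseline eye position in degrees (vertical relative to
        earth-horizontal).
    habituation_rate : float
        Gain change per minute of session time (negative = decline).
    session_time : float
        Seconds elapsed since session start when this record began; the
        habituation ramp is evaluated at ``session_time + t``.
    arrest_intervals : tuple of (start_s, end_s)
        Behavioral arrests: the slow phase decays exponentially to a held
        eccentric position and fast phases are suppressed.
    dropout_intervals : tuple of (start_s, end_s)
        Video-signal losses: pupil channels are NaN-flagged.
    excursions : tuple of (start_s, end_s, offset_deg)
        Transient eccentric holds for stationary records (saccade away,
        hold, return).
    glissade_time_constant : float
        Time constant (s) of the post-saccadic exponential glissade.
    glissade_amplitude : float
        Pulse-step mismatch (deg): the saccade overshoots its landing point
        by this much and the overshoot decays with the glissade constant.
    noise_sd : float
        Additive Gaussian position noise, degrees, per channel.
    rp : float
        Forward-projection calibration constant (camera units).
    ref_h, ref_v : float
        Reference (corneal-reflection) position in camera units.
    seed : int
        Seed for all randomness in the record.
    fast_phase_times : tuple of float
        Onset times of the generated fast phases. Output: filled in by the
        generator on the returned record's truth.
    """

    gain: float | Mapping[float, float] = 0.8
    gain_up: float | None = None
    gain_down: float | None = None
    phase_deg: float = 0.0
    drift_bias: float = 0.0
    resting_horizontal: float = 0.0
    resting_vertical: float = 0.0
    habituation_rate: float = 0.0
    session_time: float = 0.0
    arrest_intervals: tuple = ()
    dropout_intervals: tuple = ()
    excursions: tuple = ()
    glissade_time_constant: float = 0.05
    glissade_amplitude: float = 0.5
    noise_sd: float = 0.1
    rp: float = 1.0
    ref_h: float = 0.5
    ref_v: float = 0.3
    seed: int = 0
    fast_phase_times: tuple = ()

    def __post_init__(self) -> None:
        gains = (list(self.gain.values()) if isinstance(self.gain, Mapping)
                 else [self.gain])
        if self.gain_up is not None:
            gains.append(self.gain_up)
        if self.gain_down is not None:
            gains.append(self.gain_down)
        if any(g < 0 for g in gains):
            raise ValueError("gains must be >= 0")
        if self.glissade_time_constant <= 0:
            raise ValueError("glissade_time_constant must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.rp <= 0:
            raise ValueError("rp must be > 0")

    def gain_for_speed(self, speed: float) -> float:
        """Gain at a signed stimulus speed (nearest key for mappings)."""
        if isinstance(self.gain, Mapping):
            keys = np.array(sorted(self.gain), dtype=float)
            return float(self.gain[float(keys[np.argmin(np.abs(keys - speed))])])
        return float(self.gain)

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(self.gain, Mapping):
            d["gain"] = {str(k): v for k, v in self.gain.items()}
        for key in ("arrest_intervals", "dropout_intervals", "excursions",
                    "fast_phase_times"):
            d[key] = [list(x) if isinstance(x, (tuple, list)) else x for x in d[key]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        d = dict(d)
        if isinstance(d.get("gain"), dict):
            d["gain"] = {float(k): float(v) for k, v in d["gain"].items()}
        for key in ("arrest_intervals", "dropout_intervals", "excursions"):
            d[key] = tuple(tuple(x) for x in d.get(key, ()))
        d["fast_phase_times"] = tuple(d.get("fast_phase_times", ()))
        return cls(**d)


@dataclass
class RawRecord:
    """One stimulus presentation's multichannel time series.

    Channels mirror the oculography acquisition: horizontal/vertical pupil
    position, horizontal/vertical corneal-reflection reference position and
    pupil diameter (all in camera units), plus turntable position (deg) and
    planetarium velocity (deg/s). ``truth`` is present for synthetic records
    only.
    """

    sample_rate: float
    t: np.ndarray
    pupil_h: np.ndarray
    pupil_v: np.ndarray
    cr_h: np.ndarray
    cr_v: np.ndarray
    pupil_diameter: np.ndarray
    table_position: np.ndarray
    planetarium_velocity: np.ndarray
    stimulus: StimulusSpec
    truth: SimTruth | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        n = len(self.t)
        channels = ("pupil_h", "pupil_v", "cr_h", "cr_v", "pupil_diameter",
                    "table_position", "planetarium_velocity")
        for name in channels:
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length mismatch")
        dt = np.diff(self.t)
        if n > 1 and (np.any(dt <= 0)
                      or not np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-6)):
            raise ValueError("t must be strictly increasing and uniform at sample_rate")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "pupil_h": self.pupil_h, "pupil_v": self.pupil_v,
            "cr_h": self.cr_h, "cr_v": self.cr_v,
            "pupil_diameter": self.pupil_diameter,
            "table_position": self.table_position,
            "planetarium_velocity": self.planetarium_velocity,
        })


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------

def _timebase(duration: float, sample_rate: float) -> np.ndarray:
    if sample_rate <= 0:
        raise ValueError("sample_rate must be > 0")
    n = int(round(duration * sample_rate))
    return np.arange(n) / sample_rate


def _check_intervals(intervals, duration: float, what: str) -> None:
    for iv in intervals:
        t0, t1 = iv[0], iv[1]
        if not (0 <= t0 < t1 <= duration):
            raise ValueError(f"{what} interval {iv} outside record [0, {duration}]")
    starts = sorted(iv[0] for iv in intervals)
    ends = [iv[1] for iv in sorted(intervals, key=lambda x: x[0])]
    for i in range(1, len(starts)):
        if starts[i] < ends[i - 1]:
            raise ValueError(f"{what} intervals overlap")


def _interval_mask(t: np.ndarray, intervals) -> np.ndarray:
    mask = np.zeros(t.size, dtype=bool)
    for iv in intervals:
        mask |= (t >= iv[0]) & (t < iv[1])
    return mask


def _habituated(g: np.ndarray | float, truth: SimTruth, t: np.ndarray) -> np.ndarray:
    g = np.asarray(g, dtype=float) + truth.habituation_rate * (truth.session_time + t) / 60.0
    return np.maximum(g, 0.0)


def _apply_arrests(v_slow: np.ndarray, t: np.ndarray, intervals,
                   sample_rate: float) -> np.ndarray:
    """Replace slow-phase velocity inside arrest intervals with an
    exponential deceleration to zero (the eye halts eccentrically)."""
    v = v_slow.copy()
    for t0, t1 in intervals:
        i0 = int(round(t0 * sample_rate))
        i1 = int(round(t1 * sample_rate))
        i0 = max(i0, 0)
        i1 = min(i1, v.size)
        if i1 <= i0:
            continue
        v0 = v[i0]
        v[i0:i1] = v0 * np.exp(-(t[i0:i1] - t[i0]) / _ARREST_TAU)
    return v


def _insert_fast_phases(p_base: np.ndarray, sample_rate: float, baseline: float,
                        reset_threshold: float, past_center: float,
                        fast_duration: float, glissade_amp: float,
                        glissade_tau: float, suppress: np.ndarray) -> tuple[np.ndarray, list[float]]:
    """Insert position-threshold resetting fast phases into a slow-phase
    trajectory.

    Whenever eccentricity exceeds ``reset_threshold`` (outside suppressed
    spans), a fast phase of ``fast_duration`` carries the eye past center to
    ``baseline - sign * past_center``, overshooting by ``glissade_amp``; the
    overshoot then decays exponentially (the glissade). Subsequent slow-phase
    motion continues from the landing point.
    """
    if reset_threshold <= 0:
        raise ValueError("reset threshold must be > 0")
    p = p_base.copy()
    n = p.size
    nd = max(1, int(round(fast_duration * sample_rate)))
    refr = nd + max(1, int(round(_REFRACTORY * sample_rate)))
    dt = 1.0 / sample_rate
    times: list[float] = []
    i = 0
    while i < n:
        ecc = np.abs(p[i:] - baseline) > reset_threshold
        cand = np.flatnonzero(ecc & ~suppress[i:])
        if cand.size == 0:
            break
        j = i + int(cand[0])
        sgn = 1.0 if p[j] >= baseline else -1.0
        target = baseline - sgn * past_center
        land = target - sgn * glissade_amp
        jend = min(j + nd, n)
        p[j:jend] = np.linspace(p[j], land, jend - j, endpoint=False)
        if jend < n:
            rel = np.arange(n - jend) * dt
            glide = sgn * glissade_amp * (1.0 - np.exp(-rel / glissade_tau))
            p[jend:] = (p[jend:] - p[j]) + land + glide
        times.append(j * dt)
        i = jend + refr
    return p, times


def _quantize_video(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Sample-and-hold an angle trace on the 120 Hz video frame clock."""
    frame = np.floor(t * VIDEO_RATE) / VIDEO_RATE
    idx = np.clip(np.searchsorted(t, frame, side="right") - 1, 0, x.size - 1)
    return x[idx]


def _assemble(spec: StimulusSpec, truth: SimTruth, t: np.ndarray,
              sample_rate: float, h: np.ndarray, v: np.ndarray,
              table_position: np.ndarray, planetarium_velocity: np.ndarray,
              fp_times: list[float], rng: np.random.Generator,
              quantize_video: bool) -> RawRecord:
    noise = truth.noise_sd
    if quantize_video:
        h = _quantize_video(h, t)
        v = _quantize_video(v, t)
    if noise > 0:
        h = h + rng.normal(0.0, noise, t.size)
        v = v + rng.normal(0.0, noise, t.size)
    pupil_h, pupil_v = project_angles(h, v, truth.rp, truth.ref_h, truth.ref_v)
    cr_h = np.full(t.size, truth.ref_h)
    cr_v = np.full(t.size, truth.ref_v)
    diam = 1.0 + (rng.normal(0.0, 0.002, t.size) if noise > 0 else 0.0)
    drop = _interval_mask(t, truth.dropout_intervals)
    for arr in (pupil_h, pupil_v):
        arr[drop] = np.nan
    diam = np.asarray(diam, dtype=float) * np.where(drop, np.nan, 1.0)
    out_truth = replace(truth, fast_phase_times=tuple(fp_times))
    return RawRecord(sample_rate=sample_rate, t=t, pupil_h=pupil_h,
                     pupil_v=pupil_v, cr_h=cr_h, cr_v=cr_v,
                     pupil_diameter=diam, table_position=table_position,
                     planetarium_velocity=planetarium_velocity,
                     stimulus=spec, truth=out_truth)


def _build_response(spec: StimulusSpec, truth: SimTruth, t: np.ndarray,
                    sample_rate: float, v_slow: np.ndarray,
                    reset_threshold: float, past_center: float,
                    fast_duration: float, suppress: np.ndarray):
    """Integrate slow-phase velocity and insert fast phases; returns the
    response-channel position and the fast-phase onset times."""
    baseline = (truth.resting_horizontal if spec.response_channel == "h"
                else truth.resting_vertical)
    p_base = baseline + np.concatenate(
        ([0.0], cumulative_trapezoid(v_slow, t)))
    return _insert_fast_phases(
        p_base, sample_rate, baseline, reset_threshold, past_center,
        fast_duration, truth.glissade_amplitude,
        truth.glissade_time_constant, suppress)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def simulate_sinusoidal_record(spec: StimulusSpec, truth: SimTruth,
                               sample_rate: float = DEFAULT_SAMPLE_RATE,
                               reset_threshold: float = 8.0,
                               past_center: float = 2.0,
                               fast_phase_duration: float = _FAST_PHASE_DURATION,
                               quantize_video: bool = False) -> RawRecord:
    """Simulate a sinusoidal vestibular or optokinetic record.

    The slow-phase eye velocity is ``gain * drive`` shifted by
    ``phase_deg``, where the drive is the stimulus velocity in the
    compensatory direction (negated table velocity, or planetarium velocity
    as-is); a constant ``drift_bias`` rides on the vertical channel of roll
    records. Fast phases reset the eye whenever its eccentricity exceeds
    ``reset_threshold`` degrees. Identical (spec, truth) produce identical
    records.
    """
    if spec.mode != "sinusoid":
        raise ValueError("spec.mode must be 'sinusoid'")
    t = _timebase(spec.record_duration, sample_rate)
    dur = spec.record_duration
    _check_intervals(truth.arrest_intervals, dur, "arrest")
    _check_intervals(truth.dropout_intervals, dur, "dropout")
    rng = np.random.default_rng(truth.seed)

    omega = 2.0 * math.pi * spec.frequency
    phi = math.radians(truth.phase_deg)
    s = spec.stimulus_sign
    drive = s * spec.amplitude * omega * np.cos(omega * t + phi)
    if truth.gain_up is not None and truth.gain_down is not None:
        g0 = np.where(drive > 0, truth.gain_up, truth.gain_down)
    else:
        g0 = float(truth.gain) if not isinstance(truth.gain, Mapping) else truth.gain_for_speed(0.0)
    g = _habituated(g0, truth, t)
    v_slow = g * drive
    if spec.response_channel == "v":
        v_slow = v_slow + truth.drift_bias
    v_slow = _apply_arrests(v_slow, t, truth.arrest_intervals, sample_rate)
    suppress = _interval_mask(t, truth.arrest_intervals)

    p, fp_times = _build_response(spec, truth, t, sample_rate, v_slow,
                                  reset_threshold, past_center,
                                  fast_phase_duration, suppress)
    if spec.response_channel == "h":
        h, v = p, np.full(t.size, truth.resting_vertical)
    else:
        h, v = np.full(t.size, truth.resting_horizontal), p

    table = spec.amplitude * np.sin(omega * t) if spec.driver == "table" else np.zeros(t.size)
    plan = (spec.amplitude * omega * np.cos(omega * t) if spec.driver == "planetarium"
            else np.zeros(t.size))
    return _assemble(spec, truth, t, sample_rate, h, v, table, plan,
                     fp_times, rng, quantize_video)


def simulate_step_record(spec: StimulusSpec, truth: SimTruth,
                         sample_rate: float = DEFAULT_SAMPLE_RATE,
                         reset_threshold: float = 8.0,
                         past_center: float = 2.0,
                         fast_phase_duration: float = _FAST_PHASE_DURATION,
                         quantize_video: bool = False) -> RawRecord:
    """Simulate a constant-velocity optokinetic step record.

    Within each step the slow-phase eye velocity is
    ``gain(speed) * speed`` (plus the vertical drift bias for roll
    records); the planetarium-velocity channel is zero during the dark
    gaps. Behavioral arrests replace the slow phase with an exponential
    deceleration to a held eccentric position and suppress fast phases.
    """
    if spec.mode != "velocity_steps":
        raise ValueError("spec.mode must be 'velocity_steps'")
    t = _timebase(spec.record_duration, sample_rate)
    dur = spec.record_duration
    _check_intervals(truth.arrest_intervals, dur, "arrest")
    _check_intervals(truth.dropout_intervals, dur, "dropout")
    rng = np.random.default_rng(truth.seed)

    plan = np.zeros(t.size)
    v_slow = np.zeros(t.size)
    for t0, t1, speed in spec.step_windows():
        m = (t >= t0) & (t < t1)
        plan[m] = speed
        g = _habituated(truth.gain_for_speed(speed), truth, t[m])
        v_slow[m] = g * speed
    if spec.response_channel == "v":
        v_slow = v_slow + truth.drift_bias
    v_slow = _apply_arrests(v_slow, t, truth.arrest_intervals, sample_rate)
    suppress = _interval_mask(t, truth.arrest_intervals)

    p, fp_times = _build_response(spec, truth, t, sample_rate, v_slow,
                                  reset_threshold, past_center,
                                  fast_phase_duration, suppress)
    if spec.response_channel == "h":
        h, v = p, np.full(t.size, truth.resting_vertical)
    else:
        h, v = np.full(t.size, truth.resting_horizontal), p
    table = np.zeros(t.size)
    return _assemble(spec, truth, t, sample_rate, h, v, table, plan,
                     fp_times, rng, quantize_video)


def simulate_stationary_record(spec: StimulusSpec, truth: SimTruth,
                               sample_rate: float = DEFAULT_SAMPLE_RATE,
                               reset_threshold: float = 8.0,
                               past_center: float = 2.0,
                               quantize_video: bool = False) -> RawRecord:
    """Simulate a stationary (no-stimulus) record for resting-position work.

    The eye sits at the resting position; ``drift_bias`` produces a linear
    vertical drift, and ``excursions`` produce transient eccentric holds
    (saccade away, hold, saccade back) on the vertical channel.
    """
    if spec.mode != "stationary":
        raise ValueError("spec.mode must be 'stationary'")
    t = _timebase(spec.record_duration, sample_rate)
    _check_intervals(truth.dropout_intervals, spec.record_duration, "dropout")
    _check_intervals([(e[0], e[1]) for e in truth.excursions],
                     spec.record_duration, "excursion")
    rng = np.random.default_rng(truth.seed)

    v = np.full(t.size, truth.resting_vertical) + truth.drift_bias * t
    fp_times: list[float] = []
    ramp_n = max(1, int(round(_FAST_PHASE_DURATION * sample_rate)))
    for t0, t1, offset in truth.excursions:
        i0 = int(round(t0 * sample_rate))
        i1 = min(int(round(t1 * sample_rate)), t.size)
        box = np.zeros(t.size)
        box[i0:i1] = offset
        box[i0:min(i0 + ramp_n, t.size)] = np.linspace(0, offset, min(ramp_n, t.size - i0),
                                                       endpoint=False)
        if i1 < t.size:
            box[i1:min(i1 + ramp_n, t.size)] = np.linspace(
                offset, 0, min(ramp_n, t.size - i1), endpoint=False)
            box[min(i1 + ramp_n, t.size):] = 0.0
        v = v + box
        fp_times.extend([t0, t1])
    h = np.full(t.size, truth.resting_horizontal)
    zeros = np.zeros(t.size)
    return _assemble(spec, truth, t, sample_rate, h, v, zeros, zeros,
                     fp_times, rng, quantize_video)


def simulate_calibration_sweep(rp_true: float, angles, noise_sd: float = 0.0,
                               seed: int | None = None) -> pd.DataFrame:
    """Simulate a camera-yaw calibration sweep.

    Pupil displacement is ``rp_true * sin(angle)`` plus optional Gaussian
    noise; returns a table with ``camera_angle_deg`` and
    ``pupil_displacement`` columns.
    """
    angles = np.asarray(list(angles), dtype=float)
    if angles.size == 0:
        raise ValueError("angle list must not be empty")
    if np.unique(angles).size < 2:
        raise ValueError("calibration sweep needs at least two distinct angles")
    if rp_true <= 0:
        raise ValueError("rp_true must be > 0")
    disp = rp_true * np.sin(np.radians(angles))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        disp = disp + rng.normal(0.0, noise_sd, angles.size)
    return pd.DataFrame({"camera_angle_deg": angles, "pupil_displacement": disp})
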