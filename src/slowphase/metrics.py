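"""Response measures: gain/phase, hemicycle gains, speed tuning, resting
position and mean-velocity bias.

All gains are amplitude ratios of slow-phase eye velocity to stimulus
velocity (dimensionless), computed after segmentation and patching. The
stimulus velocity entering any ratio is obtained by differentiating a
stimulus *position* trace (turntable position, or the time-integral of
planetarium velocity) with the same Savitzky-Golay filter applied to eye
position, so the filter's frequency response cancels exactly in both gain
and phase. Phase is reported in degrees, positive meaning the eye leads the
stimulus, after the compensatory sign convention (eye follows the
planetarium / counter-rotates against the table) has been absorbed so that
a perfect compensatory response has gain 1 and phase 0.

Two fitting front-ends are provided in the statsmodels idiom:
:class:`SinusoidalResponseModel` and :class:`StepResponseModel`, whose
``fit()`` methods run the calibrate/segment/patch/measure chain and return
results objects with a ``summary()``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from ._filters import differentiate
from .calibration import CalibratedTrace, Rp, to_angles
from .segmentation import (DetectorConfig, SegmentLabels, segment_record)
from .simulate import RawRecord
from .stimuli import StimulusSpec

__all__ = [
    "InsufficientDataError", "UndefinedGainError",
    "CycleAverage", "GainPhase", "HemicycleGains", "SpeedTuningCurve",
    "StepGain", "RestingPosition",
    "average_cycles", "fourier_gain_phase", "hemicycle_gains",
    "step_gain", "speed_tuning", "delta_curve", "resting_position",
    "mean_velocity_bias",
    "SinusoidalResponseModel", "SinusoidalResponseResult",
    "StepResponseModel", "StepResponseResult", "analyze_record",
]


class InsufficientDataError(ValueError):
    """Too little usable data to compute a measure."""


class UndefinedGainError(ValueError):
    """The stimulus fundamental amplitude is (near) zero: gain undefined."""


def _wrap_phase(deg: float) -> float:
    """Wrap to (-180, 180]."""
    out = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if out == -180.0 else out


def _included_mask(trace: CalibratedTrace, labels: SegmentLabels | None) -> np.ndarray:
    """Samples entering slow-phase estimates: slow plus patched intervals."""
    if labels is None:
        return trace.valid.copy()
    return labels.mask("slow", "fast_phase", "glissade_excluded") & trace.valid


def _drive_position(trace: CalibratedTrace, stim: StimulusSpec) -> np.ndarray:
    """Stimulus position in the compensatory direction of the response."""
    if stim.driver == "table":
        pos = np.asarray(trace.table_position, dtype=float)
    else:
        pv = np.asarray(trace.planetarium_velocity, dtype=float)
        pos = np.concatenate(([0.0], cumulative_trapezoid(pv, trace.t)))
    return stim.stimulus_sign * pos


def _clean_velocity(x: np.ndarray, trace: CalibratedTrace,
                    labels: SegmentLabels | None,
                    cfg: DetectorConfig) -> np.ndarray:
    """Slow-phase velocity of an eye-position channel.

    The position trace is differentiated with the metric-window filter;
    fast-phase/glissade intervals (padded by the filter half-width, which
    is how far a saccadic spike leaks into neighboring velocity samples)
    are then bridged by linear interpolation between the flanking clean
    velocities -- the patching step, performed where it matters, on the
    velocity signal. Velocity near dropouts is NaN-flagged, never bridged.
    """
    from .segmentation import _runs

    v = differentiate(x, trace.sample_rate, cfg.metric_window, cfg.polyorder)
    if labels is None:
        return v
    pad = cfg.metric_window // 2
    # endpoints are medians over a half-window so a residual post-saccadic
    # tail sample cannot steer the whole bridge
    n = v.size
    for i0, i1 in _runs(labels.mask("dropout", "deleted_artifact")):
        v[max(0, i0 - pad):min(n, i1 + pad)] = np.nan
    for i0, i1 in _runs(labels.mask("fast_phase", "glissade_excluded")):
        j0, j1 = max(0, i0 - pad), min(n, i1 + pad)
        if j0 - 1 < 0 or j1 >= n:
            v[j0:j1] = np.nan
            continue
        lw = v[max(0, j0 - pad):j0]
        rw = v[j1:min(n, j1 + pad)]
        v_left = np.nanmedian(lw) if np.isfinite(lw).any() else v[j0 - 1]
        v_right = np.nanmedian(rw) if np.isfinite(rw).any() else v[j1]
        if not (np.isfinite(v_left) and np.isfinite(v_right)):
            v[j0:j1] = np.nan
            continue
        frac = (np.arange(j0, j1) - (j0 - 1)) / (j1 - (j0 - 1))
        v[j0:j1] = v_left + frac * (v_right - v_left)
    return v


def _velocities(trace: CalibratedTrace, stim: StimulusSpec,
                cfg: DetectorConfig,
                labels: SegmentLabels | None = None) -> tuple[np.ndarray, np.ndarray]:
    v_eye = _clean_velocity(trace.channel(stim.response_channel), trace,
                            labels, cfg)
    v_stim = differentiate(_drive_position(trace, stim),
                           trace.sample_rate, cfg.metric_window, cfg.polyorder)
    return v_eye, v_stim


# ---------------------------------------------------------------------------
# cycle averaging and Fourier gain/phase
# ---------------------------------------------------------------------------

@dataclass
class CycleAverage:
    """Phase-binned mean eye and stimulus velocity over one stimulus period."""

    phase: np.ndarray          # bin centers, cycles in [0, 1)
    eye_velocity: np.ndarray   # deg/s
    stim_velocity: np.ndarray  # deg/s, compensatory direction
    frequency: float           # Hz
    n_cycles: int              # clean cycles averaged


def average_cycles(patched: CalibratedTrace, stim: StimulusSpec,
                   labels: SegmentLabels | None = None, n_bins: int = 100,
                   min_cycles: int = 3,
                   cfg: DetectorConfig = DetectorConfig()) -> CycleAverage:
    """Average the patched record over stimulus cycles.

    Cycles are aligned on stimulus phase (the record starts at phase zero of
    the commanded waveform). A cycle is *clean* when at least 90% of its
    phase bins contain only usable samples; interrupted cycles are deleted,
    and within clean cycles any bin touched by an excluded sample is
    omitted from that cycle's contribution.

    Raises
    ------
    InsufficientDataError
        If fewer than ``min_cycles`` clean cycles remain.
    """
    if stim.mode != "sinusoid":
        raise ValueError("average_cycles requires a sinusoidal stimulus")
    fs = patched.sample_rate
    period = stim.period
    n_complete = int(math.floor(patched.n_samples / (period * fs)))
    if n_complete < 1:
        raise InsufficientDataError("record shorter than one stimulus cycle")
    v_eye, v_stim = _velocities(patched, stim, cfg, labels)
    usable = _included_mask(patched, labels) & np.isfinite(v_eye)

    n_keep = int(round(n_complete * period * fs))
    t = patched.t[:n_keep]
    cyc = np.minimum((t / period).astype(int), n_complete - 1)
    binno = np.minimum(((t % period) / period * n_bins).astype(int), n_bins - 1)
    cell = cyc * n_bins + binno
    n_cells = n_complete * n_bins

    total = np.bincount(cell, minlength=n_cells)
    good = np.bincount(cell[usable[:n_keep]], minlength=n_cells)
    cell_ok = (good == total) & (total > 0)
    ok_frac = cell_ok.reshape(n_complete, n_bins).mean(axis=1)
    clean = ok_frac >= 0.9
    n_clean = int(clean.sum())
    if n_clean < min_cycles:
        raise InsufficientDataError(
            f"only {n_clean} clean cycles (minimum {min_cycles})")

    use = clean[cyc] & cell_ok[cell] & usable[:n_keep]
    counts = np.bincount(binno[use], minlength=n_bins).astype(float)
    eye = np.bincount(binno[use], weights=v_eye[:n_keep][use], minlength=n_bins)
    st = np.bincount(binno[use], weights=v_stim[:n_keep][use], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        eye = eye / counts
        st = st / counts
    empty = counts == 0
    if empty.any():
        # circular linear interpolation across empty bins
        idx = np.arange(n_bins)
        for arr in (eye, st):
            arr[empty] = np.interp(idx[empty], idx[~empty], arr[~empty],
                                   period=n_bins)
    phase = (np.arange(n_bins) + 0.5) / n_bins
    return CycleAverage(phase=phase, eye_velocity=eye, stim_velocity=st,
                        frequency=stim.frequency, n_cycles=n_clean)


@dataclass
class GainPhase:
    """Gain and phase at the stimulus frequency.

    Phase convention: positive = eye leads the stimulus, in the
    compensatory direction (a perfect response is gain 1, phase 0).
    """

    gain: float
    phase_deg: float
    frequency: float
    eye_amplitude: float = float("nan")    # deg/s
    stim_amplitude: float = float("nan")   # deg/s
    n_cycles: int = 0

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if not (-180.0 < self.phase_deg <= 180.0):
            raise ValueError("phase must lie in (-180, 180]")


def fourier_gain_phase(avg: CycleAverage) -> GainPhase:
    """Fundamental-frequency gain and phase from a cycle average.

    The complex amplitude of eye and stimulus velocity at the stimulus
    frequency is extracted by discrete Fourier projection of the binned
    averages; gain is the amplitude ratio and phase the angle difference.
    """
    n = avg.phase.size
    kernel = np.exp(-2j * np.pi * np.arange(n) / n)
    ce = 2.0 / n * np.sum(avg.eye_velocity * kernel)
    cs = 2.0 / n * np.sum(avg.stim_velocity * kernel)
    if abs(cs) < 1e-9:
        raise UndefinedGainError("stimulus fundamental amplitude is ~0")
    phase = _wrap_phase(math.degrees(np.angle(ce) - np.angle(cs)))
    return GainPhase(gain=abs(ce) / abs(cs), phase_deg=phase,
                     frequency=avg.frequency, eye_amplitude=abs(ce),
                     stim_amplitude=abs(cs), n_cycles=avg.n_cycles)


# ---------------------------------------------------------------------------
# hemicycle sinusoidal regression
# ---------------------------------------------------------------------------

@dataclass
class HemicycleGains:
    """Directionally split gains from hemicycle sinusoidal regressions.

    The stimulus velocity is fit with a sinusoid; samples are split by the
    sign of the fitted velocity (positive = upward with respect to the
    recorded eye for roll stimuli), and eye and stimulus velocity in each
    hemicycle are separately regressed on ``A sin(2 pi f t) +
    B cos(2 pi f t) + C``. Each gain is the ratio of the amplitudes
    ``|Y| = sqrt(A^2 + B^2)``. A hemicycle with too few usable samples is
    reported missing (NaN) rather than imputed.
    """

    gain_up: float
    gain_down: float
    frequency: float
    coefficients: dict = field(default_factory=dict)  # (channel, hemi) -> (A, B, C)

    def __post_init__(self) -> None:
        for g in (self.gain_up, self.gain_down):
            if np.isfinite(g) and g < 0:
                raise ValueError("hemicycle gains must be >= 0")


def _sin_design(t: np.ndarray, f: float) -> np.ndarray:
    w = 2.0 * np.pi * f
    return np.column_stack([np.sin(w * t), np.cos(w * t), np.ones(t.size)])


def _ols3(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def hemicycle_gains(patched: CalibratedTrace, stim: StimulusSpec,
                    labels: SegmentLabels | None = None,
                    cfg: DetectorConfig = DetectorConfig(),
                    min_fraction: float = 0.25) -> HemicycleGains:
    """Upward/downward hemicycle gains of a sinusoidal record."""
    if stim.mode != "sinusoid":
        raise ValueError("hemicycle_gains requires a sinusoidal stimulus")
    v_eye, v_stim = _velocities(patched, stim, cfg, labels)
    usable = _included_mask(patched, labels) & np.isfinite(v_eye)
    if usable.sum() < 10:
        raise InsufficientDataError("too few usable samples for regression")
    X = _sin_design(patched.t, stim.frequency)
    stim_coef = _ols3(X[usable], v_stim[usable])
    fitted = X @ stim_coef

    gains = {}
    coefs = {}
    for name, hemi in (("up", fitted > 0), ("down", fitted < 0)):
        m = hemi & usable
        if hemi.sum() == 0 or m.sum() < min_fraction * hemi.sum():
            gains[name] = float("nan")
            continue
        ce = _ols3(X[m], v_eye[m])
        cs = _ols3(X[m], v_stim[m])
        amp_e = math.hypot(ce[0], ce[1])
        amp_s = math.hypot(cs[0], cs[1])
        if amp_s < 1e-9:
            raise UndefinedGainError("stimulus hemicycle amplitude is ~0")
        gains[name] = amp_e / amp_s
        coefs[("eye", name)] = tuple(ce)
        coefs[("stimulus", name)] = tuple(cs)
    return HemicycleGains(gain_up=gains["up"], gain_down=gains["down"],
                          frequency=stim.frequency, coefficients=coefs)


# ---------------------------------------------------------------------------
# constant-velocity steps
# ---------------------------------------------------------------------------

@dataclass
class StepGain:
    """Gain of one constant-velocity step, or the reason it is missing."""

    speed: float               # deg/s, signed
    gain: float                # NaN when unusable
    n_samples: int
    reason: str | None = None  # why the step is missing, if it is

    @property
    def usable(self) -> bool:
        return np.isfinite(self.gain)


def step_gain(trace: CalibratedTrace, labels: SegmentLabels,
              stim: StimulusSpec, window: tuple[float, float, float],
              cfg: DetectorConfig = DetectorConfig()) -> StepGain:
    """Gain of one step: mean slow-phase eye velocity over the planetarium
    velocity, using only slow/patched samples (arrests and dropouts are
    excluded). A filter-length margin at each step edge is discarded so the
    differentiator never mixes in the dark gap."""
    t0, t1, speed = window
    margin = cfg.metric_window / trace.sample_rate
    sel = (trace.t >= t0 + margin) & (trace.t < t1 - margin)
    use = sel & _included_mask(trace, labels)
    n = int(use.sum())
    if n == 0:
        reason = ("fully arrested" if (sel & labels.mask("arrest")).any()
                  else "no usable samples")
        return StepGain(speed=speed, gain=float("nan"), n_samples=0, reason=reason)
    v_eye = _clean_velocity(trace.channel(stim.response_channel), trace,
                            labels, cfg)
    use &= np.isfinite(v_eye)
    n = int(use.sum())
    if n == 0:
        return StepGain(speed=speed, gain=float("nan"), n_samples=0,
                        reason="no usable samples")
    return StepGain(speed=speed, gain=float(np.mean(v_eye[use]) / speed), n_samples=n)


@dataclass
class SpeedTuningCurve:
    """Gain as a function of signed constant stimulus speed."""

    speeds: tuple[float, ...]
    gains: tuple[float, ...]
    n: tuple[int, ...]         # usable steps per speed

    def __post_init__(self) -> None:
        if len(set(self.speeds)) != len(self.speeds):
            raise ValueError("speeds must be distinct")

    def as_series(self) -> pd.Series:
        return pd.Series(self.gains, index=pd.Index(self.speeds, name="speed"),
                         name="gain")

    def gain_at(self, speed: float) -> float:
        return dict(zip(self.speeds, self.gains))[speed]


def speed_tuning(step_gains: Iterable[StepGain]) -> SpeedTuningCurve:
    """Compile a speed-tuning curve: per-speed mean gain over usable steps."""
    by_speed: dict[float, list[float]] = {}
    for sg in step_gains:
        by_speed.setdefault(sg.speed, [])
        if sg.usable:
            by_speed[sg.speed].append(sg.gain)
    speeds = sorted(by_speed)
    gains, ns = [], []
    kept = []
    for s in speeds:
        vals = by_speed[s]
        if not vals:
            continue  # report-missing policy: speed omitted entirely
        kept.append(s)
        gains.append(float(np.mean(vals)))
        ns.append(len(vals))
    if not kept:
        raise InsufficientDataError("no usable steps at any speed")
    return SpeedTuningCurve(speeds=tuple(kept), gains=tuple(gains), n=tuple(ns))


def delta_curve(post: SpeedTuningCurve, pre: SpeedTuningCurve) -> pd.DataFrame:
    """Point-wise post minus pre gain differences, aligned on speed.

    Speeds present in only one curve are dropped with a warning.
    """
    sp_post, sp_pre = set(post.speeds), set(pre.speeds)
    common = sorted(sp_post & sp_pre)
    if not common:
        raise InsufficientDataError("no common speeds between curves")
    if sp_post != sp_pre:
        warnings.warn(f"speed sets differ; aligned on {len(common)} common speeds",
                      stacklevel=2)
    g_post = dict(zip(post.speeds, post.gains))
    g_pre = dict(zip(pre.speeds, pre.gains))
    return pd.DataFrame({
        "speed": common,
        "gain_pre": [g_pre[s] for s in common],
        "gain_post": [g_post[s] for s in common],
        "delta": [g_post[s] - g_pre[s] for s in common],
    })


# ---------------------------------------------------------------------------
# resting position and velocity bias
# ---------------------------------------------------------------------------

@dataclass
class RestingPosition:
    """Resting eye position estimate with its provenance."""

    h: float
    v: float
    method: str        # 'stable', 'mean_of_stable_spans', 'whole_record_drift'
    n_spans: int


def resting_position(trace: CalibratedTrace, labels: SegmentLabels | None = None,
                     cfg: DetectorConfig = DetectorConfig(),
                     stable_velocity: float = 1.5, min_stable: float = 0.5,
                     cluster_tol: float = 2.0,
                     dominance: float = 0.6) -> RestingPosition:
    """Resting eye position from the stable portions of a stationary record.

    Spans where eye speed stays below ``stable_velocity`` deg/s for at least
    ``min_stable`` s are collected and clustered by position
    (``cluster_tol`` deg). If one cluster dominates the stable time
    (fraction >= ``dominance``), the mean over its samples is returned and
    transient eccentric holds (saccade away, hold, return) are thereby
    excluded. If several stable positions compete ambiguously, all stable
    spans are averaged. A record with no stable span (e.g. a continuous
    linear drift) falls back to the whole-record mean.
    """
    from .segmentation import _runs

    usable = trace.valid if labels is None else (~labels.mask("dropout",
                                                              "deleted_artifact")
                                                 & trace.valid)
    if not usable.any():
        raise InsufficientDataError("no usable samples in record")
    vh = differentiate(trace.h, trace.sample_rate, cfg.metric_window, cfg.polyorder)
    vv = differentiate(trace.v, trace.sample_rate, cfg.metric_window, cfg.polyorder)
    speed = np.hypot(vh, vv)
    stable = (speed < stable_velocity) & usable
    min_len = int(round(min_stable * trace.sample_rate))
    spans = [(i0, i1) for i0, i1 in _runs(stable) if i1 - i0 >= min_len]

    def _span_range(i0: int, i1: int) -> float:
        # robust within-span travel; a slowly drifting eye passes the
        # velocity criterion but is not holding a position
        lo_h, hi_h = np.percentile(trace.h[i0:i1], [5, 95])
        lo_v, hi_v = np.percentile(trace.v[i0:i1], [5, 95])
        return max(hi_h - lo_h, hi_v - lo_v)

    spans = [s for s in spans if _span_range(*s) <= cluster_tol]
    if not spans:
        return RestingPosition(h=float(np.nanmean(trace.h[usable])),
                               v=float(np.nanmean(trace.v[usable])),
                               method="whole_record_drift", n_spans=0)

    means = np.array([[np.mean(trace.h[i0:i1]), np.mean(trace.v[i0:i1])]
                      for i0, i1 in spans])
    durs = np.array([i1 - i0 for i0, i1 in spans], dtype=float)
    # greedy clustering, longest spans first
    order = np.argsort(-durs)
    centers: list[np.ndarray] = []
    members: list[list[int]] = []
    for k in order:
        for ci, c in enumerate(centers):
            if np.linalg.norm(means[k] - c) <= cluster_tol:
                members[ci].append(k)
                w = durs[members[ci]]
                centers[ci] = np.average(means[members[ci]], axis=0, weights=w)
                break
        else:
            centers.append(means[k].copy())
            members.append([k])
    cluster_dur = np.array([durs[m].sum() for m in members])
    top = int(np.argmax(cluster_dur))
    if cluster_dur[top] >= dominance * durs.sum():
        sel = np.zeros(trace.n_samples, dtype=bool)
        for k in members[top]:
            i0, i1 = spans[k]
            sel[i0:i1] = True
        return RestingPosition(h=float(np.mean(trace.h[sel])),
                               v=float(np.mean(trace.v[sel])),
                               method="stable", n_spans=len(members[top]))
    return RestingPosition(h=float(np.mean(means[:, 0])),
                           v=float(np.mean(means[:, 1])),
                           method="mean_of_stable_spans", n_spans=len(spans))


def mean_velocity_bias(patched: CalibratedTrace, stim: StimulusSpec,
                       labels: SegmentLabels | None = None,
                       cfg: DetectorConfig = DetectorConfig()) -> float:
    """Mean vertical slow-phase eye velocity (deg/s): the DC term.

    Equals the constant coefficient C of the sinusoidal regression model
    fit to the vertical eye velocity over the full record.
    """
    vv = _clean_velocity(patched.v, patched, labels, cfg)
    usable = _included_mask(patched, labels) & np.isfinite(vv)
    if usable.sum() < 10:
        raise InsufficientDataError("too few usable samples")
    if stim.mode == "sinusoid":
        X = _sin_design(patched.t, stim.frequency)
        return float(_ols3(X[usable], vv[usable])[2])
    return float(np.mean(vv[usable]))


# ---------------------------------------------------------------------------
# model front-ends
# ---------------------------------------------------------------------------

def _resolve_rp(record: RawRecord, rp) -> float:
    if rp is not None:
        return rp.value if isinstance(rp, Rp) else float(rp)
    if record.truth is not None:
        return record.truth.rp
    raise ValueError("rp is required for records without embedded truth")


class SinusoidalResponseModel:
    """Gain/phase model of one sinusoidal vestibular or optokinetic record.

    Parameters
    ----------
    record : RawRecord
        Raw record with a sinusoidal stimulus.
    rp : Rp or float, optional
        Calibration constant; defaults to the embedded truth value for
        synthetic records.
    config : DetectorConfig, optional
        Segmentation thresholds.
    n_bins, min_cycles : int
        Cycle-average bin count per period and minimum clean cycles.
    """

    def __init__(self, record: RawRecord, rp=None,
                 config: DetectorConfig | None = None,
                 n_bins: int = 100, min_cycles: int = 3):
        if record.stimulus.mode != "sinusoid":
            raise ValueError("record is not sinusoidal")
        self.record = record
        self.rp = _resolve_rp(record, rp)
        self.config = config or DetectorConfig()
        self.n_bins = n_bins
        self.min_cycles = min_cycles

    def fit(self) -> "SinusoidalResponseResult":
        stim = self.record.stimulus
        trace = to_angles(self.record, self.rp)
        patched, labels = segment_record(trace, stim, self.config)
        avg = average_cycles(patched, stim, labels, self.n_bins,
                             self.min_cycles, self.config)
        gp = fourier_gain_phase(avg)
        hemi = hemicycle_gains(patched, stim, labels, self.config)
        bias = (mean_velocity_bias(patched, stim, labels, self.config)
                if stim.response_channel == "v" else None)
        return SinusoidalResponseResult(model=self, gain_phase=gp,
                                        hemicycle=hemi, mean_velocity_bias=bias,
                                        cycle_average=avg, labels=labels,
                                        trace=patched)


@dataclass
class SinusoidalResponseResult:
    """Fitted sinusoidal response measures."""

    model: SinusoidalResponseModel
    gain_phase: GainPhase
    hemicycle: HemicycleGains
    mean_velocity_bias: float | None
    cycle_average: CycleAverage
    labels: SegmentLabels
    trace: CalibratedTrace

    @property
    def gain(self) -> float:
        return self.gain_phase.gain

    @property
    def phase_deg(self) -> float:
        return self.gain_phase.phase_deg

    def measures(self) -> dict[str, float]:
        out = {"gain": self.gain, "phase_deg": self.phase_deg,
               "gain_up": self.hemicycle.gain_up,
               "gain_down": self.hemicycle.gain_down}
        if self.mean_velocity_bias is not None:
            out["mean_velocity_bias"] = self.mean_velocity_bias
        return out

    def summary(self) -> str:
        stim = self.model.record.stimulus
        lines = [
            "Sinusoidal response fit",
            "=======================",
            f"stimulus        {stim.driver} {stim.axis} "
            f"{stim.frequency:g} Hz +/-{stim.amplitude:g} deg ({stim.lighting})",
            f"clean cycles    {self.gain_phase.n_cycles}",
            f"gain            {self.gain:.3f}",
            f"phase           {self.phase_deg:+.1f} deg (positive = eye leads)",
            f"gain up/down    {self.hemicycle.gain_up:.3f} / {self.hemicycle.gain_down:.3f}",
        ]
        if self.mean_velocity_bias is not None:
            lines.append(f"velocity bias   {self.mean_velocity_bias:+.3f} deg/s")
        counts = self.labels.counts()
        lines.append(f"samples         " + ", ".join(
            f"{k}={v}" for k, v in counts.items() if v))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: cycle-averaged stimulus and eye velocity."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        avg = self.cycle_average
        ax.plot(avg.phase, avg.stim_velocity, label="stimulus", color="0.4")
        ax.plot(avg.phase, avg.eye_velocity, label="eye (slow phase)",
                color="C3")
        ax.set_xlabel("stimulus phase (cycles)")
        ax.set_ylabel("velocity (deg/s)")
        ax.set_title(f"gain {self.gain:.2f}, phase {self.phase_deg:+.1f} deg "
                     f"({self.gain_phase.n_cycles} cycles)")
        ax.legend(frameon=False)
        return ax


class StepResponseModel:
    """Speed-tuning model of one constant-velocity optokinetic record."""

    def __init__(self, record: RawRecord, rp=None,
                 config: DetectorConfig | None = None):
        if record.stimulus.mode != "velocity_steps":
            raise ValueError("record is not a velocity-steps record")
        self.record = record
        self.rp = _resolve_rp(record, rp)
        self.config = config or DetectorConfig()

    def fit(self) -> "StepResponseResult":
        stim = self.record.stimulus
        trace = to_angles(self.record, self.rp)
        patched, labels = segment_record(trace, stim, self.config)
        gains = [step_gain(patched, labels, stim, w, self.config)
                 for w in stim.step_windows()]
        return StepResponseResult(model=self, step_gains=gains,
                                  labels=labels, trace=patched)


@dataclass
class StepResponseResult:
    """Per-step gains of one constant-velocity record."""

    model: StepResponseModel
    step_gains: list[StepGain]
    labels: SegmentLabels
    trace: CalibratedTrace

    def tuning_curve(self) -> SpeedTuningCurve:
        return speed_tuning(self.step_gains)

    def measures(self) -> dict[str, float]:
        curve = self.tuning_curve()
        return {f"gain@{s:+g}": g for s, g in zip(curve.speeds, curve.gains)}

    def summary(self) -> str:
        lines = ["Constant-velocity OKR fit", "=========================",
                 f"{'speed':>8} {'gain':>8} {'n':>6}  note"]
        for sg in self.step_gains:
            note = sg.reason or ""
            g = f"{sg.gain:.3f}" if sg.usable else "--"
            lines.append(f"{sg.speed:>+8.1f} {g:>8} {sg.n_samples:>6}  {note}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: the speed-tuning curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.tuning_curve()
        up = [(s, g) for s, g in zip(curve.speeds, curve.gains) if s > 0]
        down = [(s, g) for s, g in zip(curve.speeds, curve.gains) if s < 0]
        for pts, label, marker in ((up, "positive speeds", "o"),
                                   (down, "negative speeds", "s")):
            if pts:
                ax.plot([abs(s) for s, _ in pts], [g for _, g in pts],
                        marker=marker, label=label)
        ax.set_xscale("log")
        ax.set_xlabel("|stimulus speed| (deg/s)")
        ax.set_ylabel("gain")
        ax.legend(frameon=False)
        return ax


def analyze_record(record: RawRecord, rp=None,
                   config: DetectorConfig | None = None):
    """Fit the model appropriate to the record's stimulus mode.

    Returns a :class:`SinusoidalResponseResult`,
    :class:`StepResponseResult`, or :class:`RestingPosition`.
    """
    mode = record.stimulus.mode
    if mode == "sinusoid":
        return SinusoidalResponseModel(record, rp=rp, config=config).fit()
    if mode == "velocity_steps":
        return StepResponseModel(record, rp=rp, config=config).fit()
    cfg = config or DetectorConfig()
    trace = to_angles(record, _resolve_rp(record, rp))
    patched, labels = segment_record(trace, record.stimulus, cfg)
    return resting_position(patched, labels, cfg)
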