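"""Labeling and removal of non-slow-phase content.

Compensatory gain must be measured on the slow phases alone. This module
labels every sample of a calibrated trace as exactly one of:

``slow``
    usable slow-phase data;
``fast_phase``
    resetting saccadic movement, later patched by linear interpolation;
``glissade_excluded``
    the first few tens of milliseconds after a fast phase, where the eye
    often shows a rapidly declining exponential (post-saccadic glissade)
    driven by pulse-step mismatch rather than the reflex pathways -- also
    patched;
``arrest``
    behavioral arrest: the animal stops generating fast phases and the eye
    halts in an eccentric position during constant-velocity stimulation --
    excluded from gain;
``dropout``
    video-signal loss or struggling artifact -- excluded, never patched;
``deleted_artifact``
    intervals that could not be patched (e.g. touching a record edge).

Detection thresholds are unavoidably conventions; they are collected in
:class:`DetectorConfig` and exposed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from ._filters import differentiate
from .calibration import CalibratedTrace
from .stimuli import StimulusSpec

__all__ = [
    "SLOW", "FAST", "GLISSADE", "ARREST", "DROPOUT", "DELETED",
    "CLASS_NAMES", "DetectorConfig", "SegmentLabels",
    "find_dropouts", "detect_fast_phases", "patch_intervals",
    "classify_step_epochs", "segment_record",
]

SLOW, FAST, GLISSADE, ARREST, DROPOUT, DELETED = range(6)
CLASS_NAMES = {
    SLOW: "slow",
    FAST: "fast_phase",
    GLISSADE: "glissade_excluded",
    ARREST: "arrest",
    DROPOUT: "dropout",
    DELETED: "deleted_artifact",
}
_NAME_TO_CLASS = {v: k for k, v in CLASS_NAMES.items()}


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds for fast-phase, arrest and dropout labeling.

    Attributes
    ----------
    velocity_threshold : float
        Absolute fast-phase velocity floor, deg/s.
    slow_peak_factor : float
        Fast phases must also exceed this multiple of the expected peak
        slow-phase speed (the stimulus peak velocity); must be > 1.
    acceleration_threshold : float
        Interval growth continues while |acceleration| exceeds this, deg/s^2.
    min_fast_duration : float
        Candidate intervals shorter than this are discarded, s.
    post_fast_exclusion : float
        Glissade-exclusion window after each fast phase, s.
    arrest_velocity_fraction : float
        A span is arrest-like when |eye velocity| falls below this fraction
        of the step's reference slow-phase speed.
    arrest_min_duration : float
        Minimum arrest span, s.
    detect_window, metric_window : int
        Savitzky-Golay differentiator windows (samples at 500 S/s) for
        detection (short, keeps saccade peaks sharp) and for velocity
        estimates entering gains (long, suppresses position noise).
    polyorder : int
        Polynomial order of the differentiator.
    dropout_guard : float
        Margin added around invalid samples, s.
    """

    velocity_threshold: float = 40.0
    slow_peak_factor: float = 3.0
    acceleration_threshold: float = 1000.0
    min_fast_duration: float = 0.006
    post_fast_exclusion: float = 0.080
    arrest_velocity_fraction: float = 0.2
    arrest_min_duration: float = 0.3
    detect_window: int = 11
    metric_window: int = 41
    arrest_window: int = 151
    polyorder: int = 2
    dropout_guard: float = 0.010

    def __post_init__(self) -> None:
        positive = ("velocity_threshold", "slow_peak_factor",
                    "acceleration_threshold", "min_fast_duration",
                    "post_fast_exclusion", "arrest_velocity_fraction",
                    "arrest_min_duration", "detect_window", "metric_window",
                    "arrest_window", "dropout_guard")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.slow_peak_factor <= 1.0:
            raise ValueError(
                "slow_peak_factor must exceed 1: a fast-phase threshold at or "
                "below the expected slow-phase peak would label slow phases as "
                "fast phases")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


@dataclass
class SegmentLabels:
    """Per-sample class labels for one record (classes mutually exclusive)."""

    t: np.ndarray
    sample_rate: float
    classes: np.ndarray
    fast_phase_directions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.t):
            raise ValueError("classes length mismatch")

    def mask(self, *names: str) -> np.ndarray:
        codes = [_NAME_TO_CLASS[n] for n in names]
        return np.isin(self.classes, codes)

    def intervals(self, name: str) -> list[tuple[float, float]]:
        """Sorted, disjoint (start_s, end_s) intervals of one class."""
        dt = 1.0 / self.sample_rate
        return [(self.t[i0], self.t[i1 - 1] + dt)
                for i0, i1 in _runs(self.classes == _NAME_TO_CLASS[name])]

    def counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.classes == code))
                for code, name in CLASS_NAMES.items()}

    def copy(self) -> "SegmentLabels":
        return SegmentLabels(self.t, self.sample_rate, self.classes.copy(),
                             self.fast_phase_directions)

    def to_frame(self):
        """BED-like interval table: one row per labeled interval."""
        import pandas as pd

        rows = []
        for code, name in CLASS_NAMES.items():
            if code == SLOW:
                continue
            for s, e in self.intervals(name):
                rows.append({"start_s": s, "end_s": e, "label": name})
        rows.sort(key=lambda r: r["start_s"])
        return pd.DataFrame(rows, columns=["start_s", "end_s", "label"])


def find_dropouts(trace: CalibratedTrace,
                  cfg: DetectorConfig = DetectorConfig()) -> SegmentLabels:
    """Label invalid samples (plus a guard margin) as dropouts."""
    classes = np.zeros(trace.n_samples, dtype=np.int8)
    guard = int(round(cfg.dropout_guard * trace.sample_rate))
    bad = ~trace.valid
    for i0, i1 in _runs(bad):
        classes[max(0, i0 - guard):min(trace.n_samples, i1 + guard)] = DROPOUT
    return SegmentLabels(t=trace.t, sample_rate=trace.sample_rate, classes=classes)


def detect_fast_phases(trace: CalibratedTrace, cfg: DetectorConfig,
                       stim: StimulusSpec,
                       labels: SegmentLabels | None = None) -> SegmentLabels:
    """Detect resetting fast phases on the stimulus's response channel.

    A sample is a fast-phase core when its smoothed speed exceeds
    ``max(velocity_threshold, slow_peak_factor * expected peak slow-phase
    speed)``; each core run is then grown outward to the flanking samples
    where both the speed has returned toward the slow-phase range and the
    acceleration has settled. A ``post_fast_exclusion`` glissade window is
    appended after every fast phase. Existing dropout labels take priority.
    """
    labels = labels.copy() if labels is not None else find_dropouts(trace, cfg)
    x = trace.channel(stim.response_channel)
    vel = differentiate(x, trace.sample_rate, cfg.detect_window, cfg.polyorder)
    acc = differentiate(vel, trace.sample_rate, cfg.detect_window, cfg.polyorder)
    expected_peak = stim.peak_velocity
    threshold = max(cfg.velocity_threshold, cfg.slow_peak_factor * expected_peak)
    grow_v = max(1.2 * expected_peak, 0.25 * threshold)

    core = np.abs(vel) > threshold
    core &= labels.classes != DROPOUT
    n = trace.n_samples
    min_len = max(1, int(round(cfg.min_fast_duration * trace.sample_rate)))
    gliss_len = int(round(cfg.post_fast_exclusion * trace.sample_rate))
    directions = []
    fast = np.zeros(n, dtype=bool)
    for i0, i1 in _runs(core):
        if i1 - i0 < min_len:
            continue
        while i0 > 0 and labels.classes[i0 - 1] == SLOW and (
                abs(vel[i0 - 1]) > grow_v or abs(acc[i0 - 1]) > cfg.acceleration_threshold):
            i0 -= 1
        while i1 < n and labels.classes[i1] == SLOW and (
                abs(vel[i1]) > grow_v or abs(acc[i1]) > cfg.acceleration_threshold):
            i1 += 1
        fast[i0:i1] = True
        peak = i0 + int(np.argmax(np.abs(vel[i0:i1])))
        directions.append(int(np.sign(vel[peak])) or 1)
        # glissade window rides on the tail of the fast phase
        j1 = min(n, i1 + gliss_len)
        sel = labels.classes[i1:j1] == SLOW
        labels.classes[i1:j1][sel] = GLISSADE
    labels.classes[fast & (labels.classes != DROPOUT)] = FAST
    labels.fast_phase_directions = tuple(directions)
    return labels


def patch_intervals(trace: CalibratedTrace, labels: SegmentLabels) -> CalibratedTrace:
    """Patch fast-phase and glissade samples by linear interpolation.

    Each contiguous fast-phase/glissade run is replaced, on both angle
    channels, by the straight line joining the last preceding and first
    following slow (or arrest) sample. Dropouts are never patched. Runs
    that touch a record edge or abut a dropout cannot be patched and are
    relabeled ``deleted_artifact`` with their samples flagged invalid.
    """
    out = trace.copy()
    patchable = labels.mask("fast_phase", "glissade_excluded")
    ok_flank = labels.mask("slow", "arrest")
    for i0, i1 in _runs(patchable):
        left = i0 - 1
        right = i1
        if left < 0 or right >= trace.n_samples or not (ok_flank[left] and ok_flank[right]):
            labels.classes[i0:i1] = DELETED
            out.valid[i0:i1] = False
            out.h[i0:i1] = np.nan
            out.v[i0:i1] = np.nan
            continue
        frac = (np.arange(i0, i1) - left) / (right - left)
        out.h[i0:i1] = trace.h[left] + frac * (trace.h[right] - trace.h[left])
        out.v[i0:i1] = trace.v[left] + frac * (trace.v[right] - trace.v[left])
        out.valid[i0:i1] = True
    return out


def classify_step_epochs(trace: CalibratedTrace, labels: SegmentLabels,
                         stim: StimulusSpec,
                         cfg: DetectorConfig = DetectorConfig()) -> SegmentLabels:
    """Label behavioral arrests within constant-velocity steps.

    For each step, a reference slow-phase speed is taken as the 75th
    percentile of |eye velocity| over the step's slow samples; spans at
    least ``arrest_min_duration`` long whose speed stays below
    ``arrest_velocity_fraction`` times the reference are labeled arrests
    (grown to where deceleration began). A step whose reference speed is
    itself negligible is marked fully arrested; downstream gain reports it
    missing. Remaining in-step samples stay slow.
    """
    if stim.mode != "velocity_steps":
        raise ValueError("classify_step_epochs applies to velocity_steps records")
    labels = labels.copy()
    x = trace.channel(stim.response_channel)
    # long window: arrests are sub-deg/s events, so the differentiator must
    # suppress position noise well below the slow-phase speed
    vel = np.abs(differentiate(x, trace.sample_rate, cfg.arrest_window, cfg.polyorder))
    min_len = max(1, int(round(cfg.arrest_min_duration * trace.sample_rate)))
    for t0, t1, speed in stim.step_windows():
        sel = (trace.t >= t0) & (trace.t < t1)
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            continue
        slow_here = labels.classes[idx] == SLOW
        if not slow_here.any():
            continue
        ref = float(np.percentile(vel[idx[slow_here]], 75))
        if ref < max(0.05 * abs(speed), 0.05):
            # no measurable slow-phase drive: either a zero-gain response
            # or a complete arrest. Call it arrested only if the step
            # opened with tracking that then halted.
            early = idx[slow_here & (trace.t[idx] < t0 + 0.5)]
            late = idx[slow_here & (trace.t[idx] >= t0 + 0.5)]
            if (early.size and late.size
                    and np.median(vel[early]) > 3 * np.median(vel[late]) + 0.3):
                labels.classes[idx[slow_here]] = ARREST
            continue
        low = vel[idx] < cfg.arrest_velocity_fraction * ref
        low &= slow_here
        for r0, r1 in _runs(low):
            if r1 - r0 < min_len:
                continue
            while r0 > 0 and slow_here[r0 - 1] and vel[idx[r0 - 1]] < 0.8 * ref:
                r0 -= 1
            while r1 < idx.size and slow_here[r1] and vel[idx[r1]] < 0.8 * ref:
                r1 += 1
            labels.classes[idx[r0:r1]] = ARREST
    return labels


def segment_record(trace: CalibratedTrace, stim: StimulusSpec,
                   cfg: DetectorConfig = DetectorConfig()
                   ) -> tuple[CalibratedTrace, SegmentLabels]:
    """Full segmentation chain: dropouts, fast phases, patching, arrests.

    Returns the patched trace and the final labels.
    """
    labels = find_dropouts(trace, cfg)
    if stim.mode != "stationary":
        labels = detect_fast_phases(trace, cfg, stim, labels)
    patched = patch_intervals(trace, labels)
    if stim.mode == "velocity_steps":
        labels = classify_step_epochs(patched, labels, stim, cfg)
    return patched, labels
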