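"""Whole-session orchestration: pre/post phases, deltas, cohort statistics
and the dose-response regression for intrafloccular injections.

A session is one animal, one treatment arm, with a battery of records
collected before and after the treatment. Every response measure is
computed per phase via the response models, treatment-related change is
always post-treatment minus pre-treatment, group contrasts use two-tailed
t-tests (unpaired unless stated), and intrafloccular series are summarized
by an ordinary least-squares regression of the per-session change against
injection volume with a saline mean +/- 2 SD reference band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import (InsufficientDataError, analyze_record, speed_tuning,
                      SpeedTuningCurve, RestingPosition,
                      SinusoidalResponseResult, StepResponseResult)
from .segmentation import DetectorConfig
from .simulate import (RawRecord, SimTruth, simulate_sinusoidal_record,
                       simulate_step_record, simulate_stationary_record)
from .stimuli import (StimulusSpec, okr_sine_spec, okr_steps_spec,
                      stationary_spec, vor_spec, vvor_spec)

__all__ = [
    "COHORTS", "TREATMENTS", "PHASES",
    "MeasureDelta", "SessionData", "SessionResult", "CohortComparison",
    "DoseResponseResult",
    "run_session", "compare_groups", "t_from_summary", "dose_response",
    "simulate_session", "sessions_to_frame",
]

COHORTS = ("young_mutant", "old_mutant", "control")
TREATMENTS = ("saline", "drug_systemic", "drug_intrafloccular", "sham")
PHASES = ("pre", "post")


@dataclass(frozen=True)
class MeasureDelta:
    """Pre/post values of one measure and their difference."""

    pre: float
    post: float
    n_pre: int = 0
    n_post: int = 0

    @property
    def delta(self) -> float:
        """Treatment-related change: post minus pre."""
        return self.post - self.pre


@dataclass
class SessionData:
    """Input records of one session, grouped by phase.

    ``records`` maps phase name ('pre'/'post') to the list of raw records
    collected in that phase, in acquisition order (the battery runs
    yaw-first before treatment and roll-first after, which matters when
    auditing habituation confounds).
    """

    animal: str
    cohort: str
    treatment: str
    records: dict[str, list[RawRecord]]
    injection_volume: float | None = None  # pL/injection
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValueError(f"cohort must be one of {COHORTS}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}")


@dataclass
class SessionResult:
    """Per-session measures with pre/post values and deltas."""

    animal: str
    cohort: str
    treatment: str
    injection_volume: float | None
    measures: dict[str, MeasureDelta]
    tuning: dict[tuple[str, str], SpeedTuningCurve] = field(default_factory=dict)
    record_order: dict[str, list[str]] = field(default_factory=dict)
    missing_phases: tuple[str, ...] = ()
    excluded: bool = False
    exclusion_reason: str = ""

    def delta(self, measure: str) -> float:
        return self.measures[measure].delta


def _measure_prefix(spec: StimulusSpec) -> str:
    if spec.mode == "stationary":
        return "resting"
    if spec.driver == "table":
        return "vor" if spec.lighting == "dark" else "vvor"
    label = f"okr_{spec.axis}"
    return label + ("_steps" if spec.mode == "velocity_steps" else "")


def _record_measures(result, prefix: str) -> dict[str, float]:
    if isinstance(result, SinusoidalResponseResult):
        out = {f"{prefix}_gain": result.gain,
               f"{prefix}_phase": result.phase_deg,
               f"{prefix}_gain_up": result.hemicycle.gain_up,
               f"{prefix}_gain_down": result.hemicycle.gain_down}
        if result.mean_velocity_bias is not None:
            out[f"{prefix}_velocity_bias"] = result.mean_velocity_bias
        return out
    if isinstance(result, StepResponseResult):
        curve = result.tuning_curve()
        return {f"{prefix}_gain@{s:+g}": g
                for s, g in zip(curve.speeds, curve.gains)}
    if isinstance(result, RestingPosition):
        return {"resting_h": result.h, "resting_v": result.v}
    raise TypeError(f"unknown result type {type(result)!r}")


def run_session(session: SessionData, rp=None,
                config: DetectorConfig | None = None) -> SessionResult:
    """Analyze every record of a session and assemble pre/post deltas.

    Measures present in only one phase yield NaN in the other phase and in
    the delta; a wholly missing phase is reported in ``missing_phases``
    rather than raising.
    """
    per_phase: dict[str, dict[str, list[float]]] = {p: {} for p in PHASES}
    tuning: dict[tuple[str, str], SpeedTuningCurve] = {}
    order: dict[str, list[str]] = {}
    step_pool: dict[tuple[str, str], list] = {}
    for phase in PHASES:
        order[phase] = []
        for rec in session.records.get(phase, []):
            prefix = _measure_prefix(rec.stimulus)
            order[phase].append(prefix)
            result = analyze_record(rec, rp=rp, config=config)
            for key, val in _record_measures(result, prefix).items():
                per_phase[phase].setdefault(key, []).append(val)
            if isinstance(result, StepResponseResult):
                step_pool.setdefault((prefix, phase), []).extend(result.step_gains)
    for (prefix, phase), gains in step_pool.items():
        tuning[(prefix, phase)] = speed_tuning(gains)

    keys = sorted(set(per_phase["pre"]) | set(per_phase["post"]))
    measures = {}
    for key in keys:
        pre_vals = [v for v in per_phase["pre"].get(key, []) if np.isfinite(v)]
        post_vals = [v for v in per_phase["post"].get(key, []) if np.isfinite(v)]
        measures[key] = MeasureDelta(
            pre=float(np.mean(pre_vals)) if pre_vals else float("nan"),
            post=float(np.mean(post_vals)) if post_vals else float("nan"),
            n_pre=len(pre_vals), n_post=len(post_vals))
    missing = tuple(p for p in PHASES if not session.records.get(p))
    return SessionResult(animal=session.animal, cohort=session.cohort,
                         treatment=session.treatment,
                         injection_volume=session.injection_volume,
                         measures=measures, tuning=tuning, record_order=order,
                         missing_phases=missing, excluded=session.excluded,
                         exclusion_reason=session.exclusion_reason)


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass
class CohortComparison:
    """Two-group t-test on one measure's deltas."""

    measure: str
    group_names: tuple[str, str]
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    t: float
    p: float
    test: str              # 'unpaired' or 'paired'
    degenerate: bool = False

    def summary(self) -> str:
        a, b = self.group_names
        lines = [f"Comparison of {self.measure} ({self.test} t-test, two-tailed)"]
        for name, m, s, n in zip(self.group_names, self.means, self.sds, self.ns):
            lines.append(f"  {name:<24} {m:+.4f} +/- {s:.4f}  (n={n})")
        lines.append(f"  t = {self.t:.3f}, p = {self.p:.4g}"
                     + ("  [degenerate variance]" if self.degenerate else ""))
        return "\n".join(lines)


def t_from_summary(mean1: float, sd1: float, n1: int,
                   mean2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Textbook pooled two-sample t statistic and two-tailed p from summary
    statistics (equal-variance form, df = n1 + n2 - 2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    if se == 0:
        return (0.0, 1.0) if mean1 == mean2 else (math.inf, 0.0)
    t = (mean1 - mean2) / se
    return t, 2.0 * stats.t.sf(abs(t), df)


def _group_values(results: Sequence[SessionResult], measure: str,
                  value: str) -> Callable[[SessionResult], float]:
    def get(r: SessionResult) -> float:
        md = r.measures[measure]
        return getattr(md, value)
    return get


def compare_groups(results: Sequence[SessionResult], measure: str,
                   group_by: str | Callable[[SessionResult], str] = "treatment",
                   groups: tuple[str, str] | None = None,
                   test: str = "unpaired", value: str = "delta",
                   include_excluded: bool = False) -> CohortComparison:
    """Two-tailed t-test of one measure between two session groups.

    Parameters
    ----------
    results : sequence of SessionResult
    measure : str
        Measure key, e.g. ``"vvor_gain"``.
    group_by : str or callable
        Attribute name or function mapping a session to its group label.
    groups : (name, name), optional
        The two group labels to compare; required when more than two labels
        are present.
    test : {'unpaired', 'paired'}
        Paired tests pair sessions by position within each group.
    value : {'delta', 'pre', 'post'}
        Which per-session quantity to compare.
    include_excluded : bool
        Sessions excluded by config are skipped unless set.
    """
    if test not in ("unpaired", "paired"):
        raise ValueError("test must be 'unpaired' or 'paired'")
    key = (lambda r: getattr(r, group_by)) if isinstance(group_by, str) else group_by
    get = _group_values(results, measure, value)
    pool: dict[str, list[float]] = {}
    for r in results:
        if r.excluded and not include_excluded:
            continue
        if measure not in r.measures:
            continue
        pool.setdefault(key(r), []).append(get(r))
    labels = tuple(sorted(pool)) if groups is None else groups
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, have {sorted(pool)}; "
                         "pass groups=(a, b)")
    a, b = (np.asarray(pool.get(l, []), dtype=float) for l in labels)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need at least 2 sessions per group")

    degenerate = False
    if test == "unpaired":
        t, p = t_from_summary(a.mean(), a.std(ddof=1), len(a),
                              b.mean(), b.std(ddof=1), len(b))
        if not math.isfinite(t):
            degenerate, t, p = True, math.inf, 0.0
        elif a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            degenerate = True
    else:
        if len(a) != len(b):
            raise ValueError("paired test needs equal group sizes")
        d = a - b
        sd = d.std(ddof=1)
        # constant shift up to float cancellation counts as degenerate
        if sd <= 1e-9 * max(1.0, float(np.abs(d).max(initial=0.0))):
            degenerate = True
            t, p = ((0.0, 1.0) if d.mean() == 0 else (math.inf, 0.0))
        else:
            t, p = stats.ttest_rel(a, b)
            t, p = float(t), float(p)
    return CohortComparison(
        measure=measure, group_names=labels,
        means=(float(a.mean()), float(b.mean())),
        sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
        ns=(len(a), len(b)), t=float(t), p=float(p), test=test,
        degenerate=degenerate)


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseResult:
    """OLS regression of per-session change against injection volume."""

    measure: str
    slope: float            # measure units per pL
    intercept: float
    r2: float
    p: float
    stderr: float           # standard error of the slope
    n: int
    saline_mean: float = float("nan")
    saline_band: tuple[float, float] = (float("nan"), float("nan"))  # mean +/- 2 SD

    def summary(self) -> str:
        lines = [f"Dose-response of {self.measure} vs injection volume (n={self.n})",
                 f"  slope     {self.slope:+.3e} per pL  (SE {self.stderr:.3e})",
                 f"  r^2       {self.r2:.3f}",
                 f"  p         {self.p:.4g}"]
        if math.isfinite(self.saline_mean):
            lines.append(f"  saline reference {self.saline_mean:+.4f} "
                         f"({self.saline_band[0]:+.4f} .. {self.saline_band[1]:+.4f})")
        return "\n".join(lines)


def dose_response(results: Sequence[SessionResult], measure: str,
                  controls: Sequence[SessionResult] = (),
                  value: str = "delta") -> DoseResponseResult:
    """Regress a measure's per-session change on injection volume.

    ``controls`` (e.g. systemic saline sessions, pooled across dosage
    series) supply the mean +/- 2 SD reference band.
    """
    pts = [(r.injection_volume, getattr(r.measures[measure], value))
           for r in results
           if not r.excluded and r.injection_volume is not None
           and measure in r.measures
           and np.isfinite(getattr(r.measures[measure], value))]
    if len(pts) < 3:
        raise InsufficientDataError("need >= 3 sessions with injection volumes")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("all injection volumes identical: regression degenerate")
    fit = stats.linregress(x, y)
    saline_mean, band = float("nan"), (float("nan"), float("nan"))
    ctrl = [getattr(r.measures[measure], value) for r in controls
            if not r.excluded and measure in r.measures
            and np.isfinite(getattr(r.measures[measure], value))]
    if len(ctrl) >= 2:
        m, s = float(np.mean(ctrl)), float(np.std(ctrl, ddof=1))
        saline_mean, band = m, (m - 2 * s, m + 2 * s)
    return DoseResponseResult(measure=measure, slope=float(fit.slope),
                              intercept=float(fit.intercept),
                              r2=float(fit.rvalue ** 2), p=float(fit.pvalue),
                              stderr=float(fit.stderr), n=len(pts),
                              saline_mean=saline_mean, saline_band=band)


# ---------------------------------------------------------------------------
# simulated sessions
# ---------------------------------------------------------------------------

_STIM_FACTORIES: dict[str, Callable[[], StimulusSpec]] = {
    "vvor": vvor_spec,
    "vor": vor_spec,
    "okr_yaw": lambda: okr_sine_spec(axis="yaw"),
    "okr_roll": lambda: okr_sine_spec(axis="roll"),
    "okr_yaw_steps": lambda: okr_steps_spec(axis="yaw"),
    "okr_roll_steps": lambda: okr_steps_spec(axis="roll"),
    "resting": stationary_spec,
}


def simulate_session(seed: int, animal: str = "sim", cohort: str = "young_mutant",
                     treatment: str = "saline",
                     stimuli: Sequence[str] = ("vvor",),
                     n_records: int = 3,
                     base_gain: float = 0.7, gain_jitter: float = 0.05,
                     habituation: float = 0.0, habituation_jitter: float = 0.0,
                     treatment_effect: float = 0.0,
                     resting_v: float = 0.0, resting_shift: float = 0.0,
                     resting_jitter: float = 0.0,
                     drift_bias: float = 0.0, noise_sd: float = 0.1,
                     injection_volume: float | None = None) -> SessionData:
    """Simulate one pre/post session with known habituation and treatment
    effects.

    The session's true pre-treatment gain is drawn once
    (``base_gain`` +/- ``gain_jitter``); its post-treatment gain adds the
    session's habituation (``habituation`` +/- ``habituation_jitter``,
    the total gain change over the session) plus ``treatment_effect``.
    Resting vertical position likewise shifts by ``resting_shift`` post
    treatment. Every record gets its own child seed, so identical arguments
    reproduce the session bit for bit.
    """
    rng = np.random.default_rng(seed)
    g0 = max(base_gain + (rng.normal(0.0, gain_jitter) if gain_jitter else 0.0), 0.02)
    hab = habituation + (rng.normal(0.0, habituation_jitter)
                         if habituation_jitter else 0.0)
    v0 = resting_v + (rng.normal(0.0, resting_jitter) if resting_jitter else 0.0)
    records: dict[str, list[RawRecord]] = {"pre": [], "post": []}
    for phase in PHASES:
        gain = g0 if phase == "pre" else max(g0 + hab + treatment_effect, 0.0)
        rest = v0 if phase == "pre" else v0 + resting_shift
        for name in stimuli:
            spec = _STIM_FACTORIES[name]()
            for _ in range(n_records):
                child = int(rng.integers(0, 2 ** 31 - 1))
                truth = SimTruth(gain=gain, drift_bias=drift_bias,
                                 resting_vertical=rest, noise_sd=noise_sd,
                                 seed=child)
                if spec.mode == "sinusoid":
                    rec = simulate_sinusoidal_record(spec, truth)
                elif spec.mode == "velocity_steps":
                    rec = simulate_step_record(spec, truth)
                else:
                    rec = simulate_stationary_record(spec, truth)
                records[phase].append(rec)
    return SessionData(animal=animal, cohort=cohort, treatment=treatment,
                       records=records, injection_volume=injection_volume)


def sessions_to_frame(results: Iterable[SessionResult]) -> pd.DataFrame:
    """Tidy table: one row per session x measure."""
    rows = []
    for r in results:
        for key, md in r.measures.items():
            rows.append({"animal": r.animal, "cohort": r.cohort,
                         "treatment": r.treatment,
                         "injection_volume": r.injection_volume,
                         "measure": key, "pre": md.pre, "post": md.post,
                         "delta": md.delta, "n_pre": md.n_pre,
                         "n_post": md.n_post, "excluded": r.excluded})
    return pd.DataFrame(rows)
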