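# Methods

This note documents the models, conventions, defaults and numerical
choices behind `slowphase`, in the order data flow through the package.

## Signal model and conventions

A record is a uniformly sampled multichannel time series (default
500 samples/s): pupil position (h, v), corneal-reflection (CR) reference
position and pupil diameter in camera units, turntable position in degrees
and planetarium velocity in deg/s. Sign conventions, fixed throughout:

* positive vertical eye position = elevation above earth-horizontal;
* positive roll-axis planetarium velocity = upward motion with respect to
  the recorded eye;
* gain is positive for a compensatory response: the eye counter-rotates
  against the table (vestibular) or follows the planetarium (optokinetic).
  The stimulus drive used in every ratio is therefore the negated table
  velocity, or the planetarium velocity as-is;
* phase is reported in (−180°, 180°], positive = eye leads the drive.

The default stimulus battery: 0.8 Hz ±4.8° yaw sinusoids in darkness (VOR)
and light (VVOR); 0.4 Hz ±4° optokinetic sinusoids about yaw and roll;
constant-velocity optokinetic steps of 4 s separated by 3.5 s dark gaps at
±{2.5, 5, 10, 20, 40} °/s (the stated range is ±2.5–40 °/s; five magnitudes
per sign is consistent with +10 °/s being the median upward speed); 40 s
per sinusoidal record.

## Calibration geometry

Yawing the camera by θ about a vertical axis through the eye displaces the
pupil image by `Rp·sin θ`; `estimate_rp` fits that slope by OLS (with an
intercept, so a constant reference offset cannot bias it) and keeps the
residual SD as a diagnostic. Angle conversion inverts the spherical
projection

    pupil_v − ref_v = Rp·sin(v_cam)
    pupil_h − ref_h = Rp·cos(v_cam)·sin(h)

The `cos(v_cam)` factor is the vertical-position correction of the
horizontal angle; switching it off (supported only to demonstrate the
error) biases |h| toward zero whenever the eye is elevated or depressed.
Elevation is expressed re: earth-horizontal by adding the mounting pitch
(default 20° nose-down). Samples whose projection argument falls outside
(−1, 1) are flagged invalid, never clipped; if more than half the record is
out of domain the conversion aborts, since that indicates a wrong `Rp` or
reference. CR subtraction (pupil − CR) is applied by default when CR
channels are present; it removes common-mode camera translation.
Horizontal angles are reported relative to the CR reference; because every
treatment contrast is a post-minus-pre difference (translation-invariant),
no per-animal recentring is applied by default — the session's own
`resting_h` measure is the natural reference when one is needed.

## Synthetic session generator

The generator exists so that every downstream stage can be validated
against known truth without animal data. For each record it builds the
slow-phase eye velocity implied by the stimulus and the truth parameters —
`gain × drive` shifted by the phase, with optional direction-split gains
(`gain_up`/`gain_down` selected by the sign of the drive), a constant
vertical `drift_bias`, and a linear habituation ramp
`gain(t) = gain + rate·(session_time + t)/60` — integrates it
(trapezoidal) to position, and then superimposes the discrete events:

* **fast phases**: whenever eccentricity exceeds a reset threshold
  (default 8°), a 20 ms saccade carries the eye past center (default 2°
  beyond), overshooting its landing point by the pulse-step mismatch
  (default 0.5°), which then decays exponentially with the glissade time
  constant (default 50 ms). A 50 ms refractory period follows. This
  threshold-reset rule reproduces resetting nystagmus without modeling the
  brainstem burst generator;
* **behavioral arrests** (step records): within the specified intervals the
  slow-phase velocity decays exponentially (τ = 0.3 s) to zero — the eye
  halts eccentrically — and fast phases are suppressed;
* **dropouts**: pupil channels are NaN over the specified intervals;
* **noise**: additive white Gaussian position noise (default SD 0.1°) on
  both angle channels.

Angles are pushed through the forward camera projection (default Rp = 1
camera unit, CR reference (0.5, 0.3)), so calibration round-trips are part
of every test. An optional stage quantizes the angle traces on the 120 Hz
video frame clock before the 500 S/s record is formed, mimicking the
two-clock acquisition chain; it is off by default because the frame-clock
jitter (~4 ms ≈ 1° of phase at 0.8 Hz) is a property of specific hardware
rather than of the method. All randomness comes from one integer seed per
record; identical inputs give bit-identical records.

What the generator does **not** emulate: torsion and 3-D kinematics,
pupil-size-dependent tracking noise, low-frequency (1/f) gaze wander,
saccade amplitude/velocity main-sequence variability, and any dependence
of gain on stimulus history beyond the linear habituation ramp. Passing
the recovery tests therefore shows the pipeline is correct for the
assumed signal structure, not that real recordings meet that structure.

## Segmentation

Every sample receives exactly one label: slow, fast_phase,
glissade_excluded, arrest, dropout or deleted_artifact. Defaults
(`DetectorConfig`), all exposed:

| parameter | default | role |
|---|---|---|
| velocity_threshold | 40 °/s | absolute fast-phase floor |
| slow_peak_factor | 3× | …or this multiple of the stimulus peak velocity, whichever is larger |
| acceleration_threshold | 1000 °/s² | interval growth criterion |
| min_fast_duration | 6 ms | discard shorter candidates |
| post_fast_exclusion | 80 ms | glissade window after each fast phase |
| arrest_velocity_fraction | 0.2 | of the step's reference slow-phase speed |
| arrest_min_duration | 0.3 s | minimum arrest span |
| detect / metric / arrest windows | 11 / 41 / 151 samples | Savitzky–Golay differentiators |
| dropout_guard | 10 ms | margin around invalid samples |

Velocity is obtained with Savitzky–Golay differentiators (polyorder 2):
an 11-sample window for detection (saccade peaks stay sharp), a 41-sample
window for the velocities entering gains (chosen so that, at the 0.1°
default position noise, the velocity noise of ~0.7 °/s keeps the phase of
a gain-0.1 response within ±2° over a 40 s record), and a 151-sample
window for arrest detection (arrests are sub-deg/s events and need
~0.1 °/s noise). The symmetric windows have zero phase, and their
amplitude attenuation cancels exactly in gain and phase because the
stimulus velocity is always produced by differentiating a stimulus
*position* trace (turntable position, or the time-integral of planetarium
velocity) with the same filter — a deliberate matched-filter design.

The post-fast exclusion window is 80 ms: with a 50 ms glissade time
constant, a shorter window leaves ~2 °/s of decaying post-saccadic
velocity at the patch boundary, which phase-locked nystagmus turns into a
gain bias of ~0.03. Eighty milliseconds is still within the "first few
tens of milliseconds" the transients occupy.

**Patching.** Gains are measures of slow-phase *velocity*, so patching is
performed on the velocity signal: each fast-phase + glissade interval,
padded by the differentiator half-width (the distance a saccadic spike
leaks into neighboring velocity samples), is bridged by linear
interpolation between the flanking clean velocities, with each endpoint
taken as the median over a half-window so a residual transient sample
cannot steer the bridge. Position-domain interpolation of the same
intervals is available (`patch_intervals`) for position-based uses; it
never alters a slow-labeled sample. Dropouts are excluded, never bridged:
velocity within a filter half-width of a dropout is NaN and the samples do
not enter any estimate. Intervals touching a record edge cannot be patched
and are deleted.

**Arrests.** Within each step, the reference slow-phase speed is the 75th
percentile of |velocity| over slow samples; spans ≥ 0.3 s below 0.2× the
reference are arrests, grown to where the deceleration began. A step whose
reference speed is itself negligible is ambiguous between a zero-gain
response and a complete arrest; it is called arrested only if its first
half-second shows tracking that then halted, otherwise it is treated as a
genuine (zero-gain) response. Alertness cannot be observed in a synthetic
record; non-alert spans in real data are expected to present as dropouts
or arrests, and manual exclusion lists are supported at the session level.

## Response measures

* **Cycle average**: complete stimulus periods are binned into 100 phase
  bins; a cycle is clean when ≥90% of its bins contain only usable
  samples; within clean cycles, any bin touched by an excluded sample is
  omitted from that cycle's contribution. Fewer than 3 clean cycles is an
  error (the acquisition convention collects at least three records per
  stimulus). Empty bins — rare — are filled by circular interpolation.
* **Fourier gain/phase**: discrete Fourier projection of the binned eye
  and stimulus velocity at the fundamental; gain = amplitude ratio,
  phase = angle difference.
* **Hemicycle gains**: OLS of per-sample (not cycle-averaged) velocity on
  `[sin 2πft, cos 2πft, 1]`, separately over the samples where the fitted
  stimulus velocity is positive (upward) or negative; gain =
  `sqrt(A²+B²)` ratio. A hemicycle with fewer than 25% usable samples is
  reported missing, never imputed. On a noiseless symmetric record the
  hemicycle gains equal the Fourier gain to numerical precision.
* **Step gains**: mean slow-phase velocity over planetarium velocity per
  step, using slow + patched samples only; a filter-length margin at each
  step edge is discarded so the differentiator never mixes in the dark
  gap. Unusable steps are reported missing with a reason. Tuning curves
  average usable steps per signed speed; difference curves align on the
  speed intersection and warn on mismatch.
* **Additive-drift law**: a constant drift v changes a step gain by
  exactly v/speed (signed) and a full-cycle sinusoidal gain not at all
  (the drift is DC). The often-quoted example — 0.2 °/s of upward drift on
  a gain-0.34 response at +2.5 °/s — gives exactly +0.08 of apparent gain
  (0.34 → 0.42); the figure of ≈0.1 sometimes attached to it is that
  number rounded, and the package asserts the exact value.
* **Resting position**: spans where eye speed stays below 1.5 °/s for
  ≥0.5 s and the within-span travel is below the 2° cluster tolerance are
  collected and clustered by position; if one cluster holds ≥60% of the
  stable time its sample mean is returned (transient eccentric
  holds — saccade away, hold, return — are thereby excluded); otherwise
  all stable spans are averaged. A record with no stable span (continuous
  drift) falls back to the whole-record mean.
* **Mean-velocity bias**: the constant coefficient C of the full-cycle
  sinusoidal regression of vertical eye velocity — the DC term.

## Sessions and statistics

Treatment-related change is always post-treatment minus pre-treatment,
per measure, with record-level values averaged within each phase. Group
contrasts are two-tailed t-tests — unpaired with the textbook pooled
variance (reproducible from summary statistics via `t_from_summary`),
paired on positionally matched sessions; zero-variance cases are reported
as degenerate rather than raising. No multiple-comparison correction is
applied by default (a Holm option exists but is off), matching the
field's reporting convention for this battery. Dose–response series are
summarized by OLS of the per-session delta on injection volume
(slope, r², p, slope SE) with a control reference band (mean ± 2 SD of
designated control sessions, pooled across series when requested).
Sessions are never auto-dropped; exclusions are explicit, carry a reason,
and are skipped by the statistics unless asked otherwise. Session-level
analysis is the default unit (matching how n is usually reported for
two-sessions-per-animal designs); animal-level averaging can be done on
the tidy output table.

The session simulator draws one true pre-treatment gain per session
(jitter SD 0.05 by default in the validation battery), adds the session's
habituation (total pre→post gain change, jitter SD 0.03) and any
treatment effect to the post-phase records, so the expected delta
decomposes exactly into habituation + effect. These jitters stand in for
the between-session variability of real animals; the reported group SDs
in comparable experiments are ~0.06–0.09, so the simulated arms are, if
anything, better behaved than real cohorts.

## Dosimetry

Pure unit-converting arithmetic, no compartmental kinetics. Ejectate
volume `π·d³/6` (µm³ → pL is ÷1000). Dilution of an injected bolus into
the accessible interstitial space: the default convention keeps the bolus
in the denominator, `V/(V + f·V_t)` (mass conservation), giving 19.2% for
20 nL into 0.21 × 400 nL; the interstitial-only variant `V/(f·V_t)` =
23.8% is available behind a flag because published arithmetic is
ambiguous between the two — both round to "about 20%". Peak serum =
dose/Vd (mg/kg over mL/kg ×10⁶ → ng/mL); CSF concentration = serum ×
CSF:serum ratio ÷ molar mass (ng/mL is µg/L, so ÷ g/mol gives µM). The
4-AP molar mass is fixed at 94.12 g/mol.

## Validation battery sizes

The acceptance script and test suite validate on: 100 seeded sinusoidal
records spanning gains 0.1–1.0 (with 0.5 °/s drift so resetting fast
phases occur); 50 asymmetric + 15 symmetric hemicycle records; the
10-speed drift-law pair at zero noise; 5 dense-nystagmus guard records
(reset threshold 3°, ~64 fast phases each); 8 replicates of 12+12-session
habituation arms; and 20 replicates of 40-session null dose–response
series plus one 40-session positive-slope series. These sizes give the
recovery statistics stable second decimals while keeping the whole battery
around a minute of CPU.

## Known limitations

* The generator's event models (threshold-reset fast phases, exponential
  arrests and glissades, white position noise) are stylized; detector
  thresholds tuned here should be re-examined on real recordings.
* Habituation is a linear ramp in gain; real habituation may saturate or
  interact with stimulus history.
* The vertical drift bias applies to the vertical channel only; a
  horizontal drift term would be needed to study the analogous confound
  for yaw responses.
* No torsional eye position or 3-D kinematics; the spherical projection
  assumes rotations about the camera axes.
* Phase estimates inherit the frame-clock jitter when the 120 Hz
  quantization stage is enabled (~1° at 0.8 Hz); the default pipeline does
  not model it.
* The resting-position clustering can report a slightly biased mean when
  noise fragments a slowly drifting record into short locally-stable
  spans; the unambiguous cases (stable hold, transient excursions, clean
  drift) are handled exactly.
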