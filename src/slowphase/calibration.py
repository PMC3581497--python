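"""Camera-yaw calibration and conversion of pupil positions to eye angles.

The video-oculography camera reports pupil and corneal-reflection (CR)
positions in arbitrary camera units. Yawing the camera by a known angle
``theta`` about a vertical axis through the eye displaces the pupil image by
``Rp * sin(theta)``, where ``Rp`` is the effective distance from the pupil
to the ocular rotation center expressed in camera units. A short calibration
sweep over several camera angles therefore yields ``Rp`` as the slope of
displacement against ``sin(theta)``, after which eye rotations are recovered
by inverting the same spherical projection:

    pupil_v - ref_v = Rp * sin(v)
    pupil_h - ref_h = Rp * cos(v) * sin(h)

The ``cos(v)`` factor is the vertical-position correction of the horizontal
angle: an elevated or depressed eye forshortens the horizontal projection,
and ignoring it biases ``|h|`` toward zero whenever ``v != 0``.

Vertical angles are reported as elevation relative to the earth-horizontal
plane. The animal is mounted pitched nose-down by ``MOUNT_PITCH_DEG``, so the
camera-frame elevation is offset by that amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import RawRecord
    from .stimuli import StimulusSpec

__all__ = [
    "MOUNT_PITCH_DEG",
    "Rp",
    "CalibratedTrace",
    "CalibrationError",
    "estimate_rp",
    "project_angles",
    "to_angles",
]

#: Head mounting pitch in degrees (negative = nose-down); the lambda-bregma
#: axis is pitched 20 deg nose-down in the recording apparatus.
MOUNT_PITCH_DEG = -20.0


class CalibrationError(ValueError):
    """Raised when a calibration fit or angle conversion is unusable."""


@dataclass(frozen=True)
class Rp:
    """Pupil-to-rotation-center distance in camera units per unit sine.

    Attributes
    ----------
    value : float
        Fitted slope of pupil displacement vs. sin(camera angle).
    stderr : float or None
        Standard error of the slope (None for exactly determined fits).
    resid_sd : float
        Residual standard deviation of the calibration fit.
    n_points : int
        Number of sweep points used.
    """

    value: float
    stderr: float | None = None
    resid_sd: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise CalibrationError(f"Rp must be finite and > 0, got {self.value}")


def estimate_rp(sweep, angle_col: str = "camera_angle_deg",
                disp_col: str = "pupil_displacement") -> Rp:
    """Estimate Rp from a camera-yaw calibration sweep.

    Parameters
    ----------
    sweep : pandas.DataFrame or (n, 2) array-like
        Camera yaw angle (degrees) and pupil displacement (camera units).
        The camera is yawed about a vertical axis through the recorded eye,
        typically over +/-10 degrees.

    Returns
    -------
    Rp
        Least-squares slope of displacement vs. sin(angle) (an intercept is
        included so a constant reference offset does not bias the slope),
        with fit residual diagnostics.

    Raises
    ------
    CalibrationError
        If fewer than two distinct angles are supplied, or the fitted slope
        is not positive (which indicates a sign-convention mismatch between
        the camera-angle and displacement conventions: flip the sign of one).
    """
    if isinstance(sweep, pd.DataFrame):
        angles = np.asarray(sweep[angle_col], dtype=float)
        disp = np.asarray(sweep[disp_col], dtype=float)
    else:
        arr = np.asarray(sweep, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("sweep must be a DataFrame or an (n, 2) array")
        angles, disp = arr[:, 0], arr[:, 1]
    if angles.size < 2 or np.unique(angles).size < 2:
        raise CalibrationError(
            "calibration sweep needs at least two distinct camera angles")

    import statsmodels.api as sm

    x = np.sin(np.radians(angles))
    X = sm.add_constant(x)
    fit = sm.OLS(disp, X).fit()
    slope = float(fit.params[1])
    if slope <= 0:
        raise CalibrationError(
            f"fitted calibration slope is {slope:.4g} <= 0; pupil displacement "
            "should increase with sin(camera angle). Check the sign convention "
            "of the camera-angle or displacement channel.")
    stderr = float(fit.bse[1]) if angles.size > 2 else None
    resid_sd = float(np.std(fit.resid, ddof=min(2, angles.size - 1)))
    return Rp(value=slope, stderr=stderr, resid_sd=resid_sd, n_points=int(angles.size))


def project_angles(h_deg, v_deg, rp: float, ref_h: float = 0.0, ref_v: float = 0.0,
                   mount_pitch_deg: float = MOUNT_PITCH_DEG):
    """Forward spherical projection of eye angles to camera pupil positions.

    Inverse of :func:`to_angles`; used by the synthetic generator so that
    calibration round-trips are exact.
    """
    v_cam = np.radians(np.asarray(v_deg, dtype=float) - mount_pitch_deg)
    h = np.radians(np.asarray(h_deg, dtype=float))
    pupil_v = ref_v + rp * np.sin(v_cam)
    pupil_h = ref_h + rp * np.cos(v_cam) * np.sin(h)
    return pupil_h, pupil_v


@dataclass
class CalibratedTrace:
    """Angular eye position with validity flags and stimulus channels.

    ``h`` is the horizontal angle (degrees; positive toward the recorded
    side, reported relative to whatever reference the caller supplied),
    ``v`` the elevation above earth-horizontal. ``valid`` is False wherever
    the pupil signal was lost or the projection could not be inverted.
    The stimulus channels and spec ride along for downstream analysis.
    """

    t: np.ndarray
    h: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    sample_rate: float
    table_position: np.ndarray | None = None
    planetarium_velocity: np.ndarray | None = None
    stimulus: "StimulusSpec | None" = None
    source: "RawRecord | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("h", "v", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length mismatch")
        finite = self.valid & np.isfinite(self.h) & np.isfinite(self.v)
        if np.any(np.abs(self.h[finite]) >= 90) or np.any(np.abs(self.v[finite]) >= 90):
            raise ValueError("calibrated angles must lie within (-90, 90) degrees")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def channel(self, name: str) -> np.ndarray:
        """Return the 'h' or 'v' position channel."""
        if name not in ("h", "v"):
            raise KeyError(name)
        return self.h if name == "h" else self.v

    def copy(self) -> "CalibratedTrace":
        return CalibratedTrace(
            t=self.t.copy(), h=self.h.copy(), v=self.v.copy(),
            valid=self.valid.copy(), sample_rate=self.sample_rate,
            table_position=None if self.table_position is None else self.table_position.copy(),
            planetarium_velocity=(None if self.planetarium_velocity is None
                                  else self.planetarium_velocity.copy()),
            stimulus=self.stimulus, source=self.source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "h_deg": self.h, "v_deg": self.v,
                             "valid": self.valid.astype(int)})


def to_angles(rec: "RawRecord", rp: Rp | float, offsets: tuple[float, float] | None = None,
              subtract_cr: bool = True, vertical_correction: bool = True,
              mount_pitch_deg: float = MOUNT_PITCH_DEG,
              max_invalid_fraction: float = 0.5) -> CalibratedTrace:
    """Convert a raw record's pupil channels to angular eye position.

    Parameters
    ----------
    rec : RawRecord
        Raw multichannel record.
    rp : Rp or float
        Calibration constant from :func:`estimate_rp`.
    offsets : (ref_h, ref_v), optional
        Reference pupil position corresponding to zero horizontal angle and
        zero camera-frame elevation. Defaults to (0, 0), which is correct
        when CR subtraction is enabled and the CR marks the reference.
    subtract_cr : bool
        Subtract the corneal-reflection channels from the pupil channels
        before calibration (removes common-mode camera translation).
    vertical_correction : bool
        Scale the horizontal projection by cos(vertical angle). Disabling
        this reproduces the small-angle approximation, which biases ``|h|``
        low whenever the eye is elevated or depressed; exposed only so the
        bias can be demonstrated.
    mount_pitch_deg : float
        Head mounting pitch applied to express elevation relative to
        earth-horizontal (default 20 deg nose-down).

    Raises
    ------
    CalibrationError
        If more than ``max_invalid_fraction`` of samples cannot be
        inverted (projection argument outside [-1, 1]).
    """
    rp_val = rp.value if isinstance(rp, Rp) else float(rp)
    if not np.isfinite(rp_val) or rp_val <= 0:
        raise CalibrationError("rp must be finite and positive")
    ref_h, ref_v = (0.0, 0.0) if offsets is None else offsets
    if not (np.isfinite(ref_h) and np.isfinite(ref_v)):
        raise CalibrationError("offsets must be finite")

    ph = np.asarray(rec.pupil_h, dtype=float)
    pv = np.asarray(rec.pupil_v, dtype=float)
    if subtract_cr and rec.cr_h is not None:
        ph = ph - np.asarray(rec.cr_h, dtype=float)
        pv = pv - np.asarray(rec.cr_v, dtype=float)
    dh = ph - ref_h
    dv = pv - ref_v

    arg_v = dv / rp_val
    lost = ~np.isfinite(arg_v)
    bad_v = np.isfinite(arg_v) & (np.abs(arg_v) >= 1.0)
    v_cam = np.arcsin(np.clip(np.where(np.isfinite(arg_v), arg_v, 0.0), -0.999999, 0.999999))
    cos_v = np.cos(v_cam) if vertical_correction else np.ones_like(v_cam)
    arg_h = dh / (rp_val * cos_v)
    lost |= ~np.isfinite(arg_h)
    bad_h = np.isfinite(arg_h) & (np.abs(arg_h) >= 1.0)
    h = np.degrees(np.arcsin(np.clip(np.where(np.isfinite(arg_h), arg_h, 0.0),
                                     -0.999999, 0.999999)))
    v = np.degrees(v_cam) + mount_pitch_deg

    valid = ~(lost | bad_v | bad_h)
    # never clip silently: out-of-domain samples become invalid NaN
    h = np.where(valid, h, np.nan)
    v = np.where(valid, v, np.nan)
    oor = bad_v | bad_h
    if oor.mean() > max_invalid_fraction:
        raise CalibrationError(
            f"{oor.mean():.0%} of samples fall outside the projection domain; "
            "the calibration constant or reference offsets are wrong")

    return CalibratedTrace(
        t=np.asarray(rec.t, dtype=float), h=h, v=v, valid=valid,
        sample_rate=float(rec.sample_rate),
        table_position=np.asarray(rec.table_position, dtype=float),
        planetarium_velocity=np.asarray(rec.planetarium_velocity, dtype=float),
        stimulus=rec.stimulus, source=rec)
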