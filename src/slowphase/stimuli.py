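"""Stimulus descriptions for the rotational/optokinetic test battery.

A recording session probes compensatory eye movements with a small battery
of natural stimuli: sinusoidal rotation of the animal (turntable; VOR in
darkness, VVOR in the light), sinusoidal rotation of the visual surround
(planetarium; optokinetic reflex, OKR) about the yaw or roll axis, and
constant-velocity optokinetic steps of alternating direction used to build
speed-tuning curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

__all__ = [
    "StimulusSpec",
    "vor_spec",
    "vvor_spec",
    "okr_sine_spec",
    "okr_steps_spec",
    "stationary_spec",
    "DEFAULT_STEP_SPEEDS",
]

#: Default constant-velocity test speeds (deg/s), five magnitudes of each sign.
DEFAULT_STEP_SPEEDS: tuple[float, ...] = (
    2.5, -2.5, 5.0, -5.0, 10.0, -10.0, 20.0, -20.0, 40.0, -40.0,
)


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus presentation.

    Parameters
    ----------
    axis : {"yaw", "roll"}
        Rotation axis. Yaw stimuli drive horizontal eye movement, roll
        (optokinetic only) drives vertical eye movement.
    mode : {"sinusoid", "velocity_steps", "stationary"}
        Waveform class. ``stationary`` is the no-stimulus condition used
        to measure resting eye position.
    driver : {"table", "planetarium"}
        Whether the turntable (vestibular) or the planetarium projector
        (optokinetic) delivers the stimulus. Determines the compensatory
        sign convention: a positive gain means the eye counter-rotates
        against the table, or follows the planetarium.
    frequency : float
        Sinusoid frequency in Hz (sinusoid mode only).
    amplitude : float
        Sinusoid position amplitude in degrees (sinusoid mode only).
    speeds : sequence of float
        Signed constant speeds in deg/s (velocity_steps mode only).
    step_duration, gap_duration : float
        Seconds of constant-velocity drive and of intervening darkness.
    record_duration : float
        Total record length in seconds. For velocity_steps the default is
        derived from the speed list.
    lighting : {"light", "dark"}
        Dark turntable rotation is the VOR; the same rotation with the lit,
        stationary planetarium surround is the VVOR.
    """

    axis: str = "yaw"
    mode: str = "sinusoid"
    driver: str = "table"
    frequency: float = 0.8
    amplitude: float = 4.8
    speeds: tuple[float, ...] = ()
    step_duration: float = 4.0
    gap_duration: float = 3.5
    record_duration: float = 40.0
    lighting: str = "light"

    def __post_init__(self) -> None:
        if self.axis not in ("yaw", "roll"):
            raise ValueError(f"axis must be 'yaw' or 'roll', got {self.axis!r}")
        if self.mode not in ("sinusoid", "velocity_steps", "stationary"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.driver not in ("table", "planetarium"):
            raise ValueError(f"driver must be 'table' or 'planetarium', got {self.driver!r}")
        if self.lighting not in ("light", "dark"):
            raise ValueError(f"lighting must be 'light' or 'dark', got {self.lighting!r}")
        if self.mode == "sinusoid":
            if not (self.frequency > 0):
                raise ValueError("sinusoid frequency must be > 0")
            if not (self.amplitude > 0):
                raise ValueError("sinusoid amplitude must be > 0")
        if self.mode == "velocity_steps":
            if len(self.speeds) == 0:
                raise ValueError("velocity_steps requires a non-empty speed list")
            if any(s == 0 for s in self.speeds):
                raise ValueError("step speeds must be nonzero")
            if self.driver != "planetarium":
                raise ValueError("constant-velocity steps are optokinetic (driver='planetarium')")
        if self.axis == "roll" and self.driver == "table":
            raise ValueError("the turntable rotates about yaw only")
        if self.step_duration <= 0 or self.gap_duration <= 0 or self.record_duration <= 0:
            raise ValueError("durations must be > 0")

    @property
    def period(self) -> float:
        """Stimulus period in seconds (sinusoid mode)."""
        if self.mode != "sinusoid":
            raise ValueError("period defined for sinusoids only")
        return 1.0 / self.frequency

    @property
    def peak_velocity(self) -> float:
        """Peak stimulus velocity in deg/s."""
        import math

        if self.mode == "sinusoid":
            return 2.0 * math.pi * self.frequency * self.amplitude
        if self.mode == "velocity_steps":
            return max(abs(s) for s in self.speeds)
        return 0.0

    @property
    def response_channel(self) -> str:
        """Eye-position channel the stimulus drives: 'h' (yaw) or 'v' (roll)."""
        return "h" if self.axis == "yaw" else "v"

    @property
    def stimulus_sign(self) -> float:
        """+1 if the eye follows the stimulus (optokinetic), -1 if it
        counter-rotates (vestibular); used so reported gains are positive."""
        return 1.0 if self.driver == "planetarium" else -1.0

    def step_windows(self) -> list[tuple[float, float, float]]:
        """(start_s, end_s, speed) for each constant-velocity step.

        Each step is preceded by a dark gap during which the planetarium
        reverses and re-accelerates, so step k occupies
        ``[k*(gap+step)+gap, (k+1)*(gap+step))``.
        """
        if self.mode != "velocity_steps":
            raise ValueError("step_windows defined for velocity_steps only")
        out = []
        cycle = self.gap_duration + self.step_duration
        for k, speed in enumerate(self.speeds):
            t0 = k * cycle + self.gap_duration
            out.append((t0, t0 + self.step_duration, float(speed)))
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["speeds"] = list(self.speeds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        d = dict(d)
        d["speeds"] = tuple(d.get("speeds", ()))
        return cls(**d)


def vor_spec(frequency: float = 0.8, amplitude: float = 4.8,
             record_duration: float = 40.0) -> StimulusSpec:
    """Yaw-axis vestibular sinusoid in darkness (VOR)."""
    return StimulusSpec(axis="yaw", mode="sinusoid", driver="table",
                        frequency=frequency, amplitude=amplitude,
                        record_duration=record_duration, lighting="dark")


def vvor_spec(frequency: float = 0.8, amplitude: float = 4.8,
              record_duration: float = 40.0) -> StimulusSpec:
    """Yaw-axis vestibular sinusoid with lit, stationary surround (VVOR)."""
    return StimulusSpec(axis="yaw", mode="sinusoid", driver="table",
                        frequency=frequency, amplitude=amplitude,
                        record_duration=record_duration, lighting="light")


def okr_sine_spec(axis: str = "roll", frequency: float = 0.4,
                  amplitude: float = 4.0, record_duration: float = 40.0) -> StimulusSpec:
    """Sinusoidal optokinetic stimulus (planetarium)."""
    return StimulusSpec(axis=axis, mode="sinusoid", driver="planetarium",
                        frequency=frequency, amplitude=amplitude,
                        record_duration=record_duration, lighting="light")


def okr_steps_spec(axis: str = "roll",
                   speeds: Sequence[float] = DEFAULT_STEP_SPEEDS,
                   step_duration: float = 4.0,
                   gap_duration: float = 3.5) -> StimulusSpec:
    """Constant-velocity optokinetic steps of alternating direction."""
    speeds = tuple(float(s) for s in speeds)
    duration = len(speeds) * (step_duration + gap_duration)
    return StimulusSpec(axis=axis, mode="velocity_steps", driver="planetarium",
                        speeds=speeds, step_duration=step_duration,
                        gap_duration=gap_duration, record_duration=duration,
                        lighting="light")


def stationary_spec(record_duration: float = 40.0, axis: str = "roll") -> StimulusSpec:
    """Stationary, lit condition used for resting eye position."""
    return StimulusSpec(axis=axis, mode="stationary", driver="planetarium",
                        record_duration=record_duration, lighting="light")
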