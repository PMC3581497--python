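"""Micro-injection and systemic dosimetry arithmetic for 4-aminopyridine.

Covers the three back-of-envelope calculations that anchor the drug
experiments:

* **Ejectate volumetry** — pressure-injected volume per pulse is measured
  by ejecting into a paraffin-oil bath, photographing the sphere of
  ejectate and converting its diameter to a volume (``pi d^3 / 6``).
* **Intrafloccular dilution** — an injected bolus expanding into the
  accessible interstitial space of the target lobule (about 400 nL of
  tissue, of which ~21% is interstitial) dilutes the drug concentration;
  20 nL into such a space falls to roughly 20% of the pipette
  concentration.
* **Systemic dose -> brain exposure** — a subcutaneous bolus, if fully
  absorbed and equilibrated over the volume of distribution before
  elimination, sets a ceiling on peak serum level (``dose / Vd``); the
  CSF:serum partition ratio and the molar mass then convert that to a peak
  CSF concentration in micromolar.

All functions are pure unit-converting arithmetic; no compartmental
kinetics are modeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MOLAR_MASS_4AP",
    "PkParams",
    "EjectionGeometry",
    "DilutionModel",
    "ejection_volume",
    "dilution_fraction",
    "serum_peak",
    "csf_molar",
]

#: Molar mass of 4-aminopyridine (C5H6N2), g/mol.
MOLAR_MASS_4AP = 94.12


@dataclass(frozen=True)
class PkParams:
    """Systemic dosing parameters.

    dose in mg/kg; volume_of_distribution in mL/kg; csf_serum_ratio
    dimensionless; molar_mass in g/mol.
    """

    dose: float = 1.25
    volume_of_distribution: float = 1036.0
    csf_serum_ratio: float = 0.21
    molar_mass: float = MOLAR_MASS_4AP

    def __post_init__(self) -> None:
        for name in ("dose", "volume_of_distribution", "csf_serum_ratio",
                     "molar_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def serum_peak(self) -> float:
        """Peak serum level in ng/mL."""
        return serum_peak(self.dose, self.volume_of_distribution)

    def csf_peak_molar(self) -> float:
        """Peak CSF concentration in µM."""
        return csf_molar(self.serum_peak(), self.csf_serum_ratio, self.molar_mass)


@dataclass(frozen=True)
class EjectionGeometry:
    """Sphere-of-ejectate measurement: diameter (µm) -> volume (pL)."""

    sphere_diameter: float  # µm

    def __post_init__(self) -> None:
        if self.sphere_diameter <= 0:
            raise ValueError("sphere_diameter must be > 0")

    @property
    def volume_per_injection(self) -> float:
        """Ejectate volume per injection, pL (exactly pi d^3 / 6)."""
        return ejection_volume(self.sphere_diameter)


@dataclass(frozen=True)
class DilutionModel:
    """Bolus dilution into accessible interstitial space.

    injected_volume and tissue_volume in nL; interstitial_fraction in
    (0, 1].
    """

    injected_volume: float = 20.0
    tissue_volume: float = 400.0
    interstitial_fraction: float = 0.21

    def __post_init__(self) -> None:
        if self.injected_volume <= 0 or self.tissue_volume < 0:
            raise ValueError("volumes must be positive")
        if not (0 < self.interstitial_fraction <= 1):
            raise ValueError("interstitial_fraction must be in (0, 1]")

    def fraction(self, include_injectate: bool = True) -> float:
        return dilution_fraction(self, include_injectate=include_injectate)


def ejection_volume(diameter_um: float) -> float:
    """Volume of a sphere of ejectate, in pL, from its diameter in µm.

    1 pL = 1e3 µm^3, so ``V[pL] = pi d^3 / 6 * 1e-3`` with d in µm.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be > 0")
    return math.pi * diameter_um ** 3 / 6.0 * 1e-3


def dilution_fraction(m: DilutionModel, include_injectate: bool = True) -> float:
    """Fraction of the pipette concentration remaining after dilution.

    With ``include_injectate`` (default) the injected bolus itself is part
    of the final volume (mass conservation):
    ``injected / (injected + f * tissue)``. The flagged alternative uses
    the interstitial volume alone in the denominator,
    ``injected / (f * tissue)`` — the arithmetic that is sometimes quoted
    instead; for a 20 nL bolus into 0.21 x 400 nL the two conventions give
    19.2% and 23.8%, both "about 20%".
    """
    interstitial = m.interstitial_fraction * m.tissue_volume
    denom = m.injected_volume + interstitial if include_injectate else interstitial
    if denom <= 0:
        raise ZeroDivisionError("dilution denominator is zero")
    return m.injected_volume / denom


def serum_peak(dose_mg_per_kg: float, vd_ml_per_kg: float) -> float:
    """Peak serum level in ng/mL from dose (mg/kg) and Vd (mL/kg).

    mg/kg over mL/kg is mg/mL; x 1e6 gives ng/mL.
    """
    if dose_mg_per_kg < 0:
        raise ValueError("dose must be >= 0")
    if vd_ml_per_kg <= 0:
        raise ValueError("volume of distribution must be > 0")
    return dose_mg_per_kg / vd_ml_per_kg * 1e6


def csf_molar(serum_ng_per_ml: float, ratio: float, molar_mass: float = MOLAR_MASS_4AP) -> float:
    """CSF concentration in µM from serum level (ng/mL) and CSF:serum ratio.

    ng/mL is µg/L; dividing by molar mass (g/mol) gives µmol/L = µM.
    """
    if serum_ng_per_ml < 0 or ratio < 0:
        raise ValueError("serum level and ratio must be >= 0")
    if molar_mass <= 0:
        raise ValueError("molar mass must be > 0")
    return serum_ng_per_ml * ratio / molar_mass
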