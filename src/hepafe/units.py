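"""Liver iron concentration (LIC) units and the linear R2*-to-LIC calibration.

LIC is reported per gram of dry liver tissue, either in mg Fe/g or in
µmol Fe/g; the two scales are related by the molar mass of iron
(55.845 g/mol), so 1 mg/g ≈ 17.906 µmol/g.  The clinical upper limit of
normal is 2 mg/g (≈36 µmol/g).

R2* (= 1000/T2*[ms], in Hz) rises approximately linearly with iron load at
1.5 T, which is why a simple linear regression ``LIC = slope·R2* + intercept``
is the standard conversion for gradient-echo relaxometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "IRON_MOLAR_MASS_G_PER_MOL",
    "LICUnits",
    "LICValue",
    "LinearR2sCalibration",
    "HANKINS_CALIBRATION",
    "convert_lic",
    "lic_from_r2s",
    "r2s_from_lic",
    "classify_overload",
]

#: Molar mass of iron, g/mol.  Single constant behind both unit anchors.
IRON_MOLAR_MASS_G_PER_MOL = 55.845

#: mg/g per µmol/g: 1 µmol Fe = 55.845 µg = 0.055845 mg.
MG_PER_UMOL = IRON_MOLAR_MASS_G_PER_MOL / 1000.0
_MG_PER_UMOL = MG_PER_UMOL


class LICUnits(str, Enum):
    """Supported LIC unit scales (both per gram of dry liver)."""

    MG_PER_G_DRY = "mg_per_g_dry"
    UMOL_PER_G_DRY = "umol_per_g_dry"


@dataclass(frozen=True)
class LICValue:
    """A liver iron concentration with explicit units.

    Parameters
    ----------
    value : float
        Non-negative concentration.
    units : LICUnits or str
        ``mg_per_g_dry`` or ``umol_per_g_dry``.
    """

    value: float
    units: LICUnits

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", LICUnits(self.units))
        if self.value < 0:
            raise ValueError(f"LIC must be non-negative, got {self.value}")

    def to(self, target: LICUnits | str) -> "LICValue":
        return convert_lic(self, target)


def convert_lic(v: LICValue, target_units: LICUnits | str) -> LICValue:
    """Convert a LIC value between mg/g and µmol/g dry weight.

    The conversion uses the iron molar mass only, so round trips are exact
    to floating-point precision.
    """
    target = LICUnits(target_units)
    if v.units == target:
        return v
    if v.units == LICUnits.UMOL_PER_G_DRY and target == LICUnits.MG_PER_G_DRY:
        return LICValue(v.value * _MG_PER_UMOL, target)
    if v.units == LICUnits.MG_PER_G_DRY and target == LICUnits.UMOL_PER_G_DRY:
        return LICValue(v.value / _MG_PER_UMOL, target)
    raise ValueError(f"unknown unit pair {v.units} -> {target}")


@dataclass(frozen=True)
class LinearR2sCalibration:
    """Linear R2*→LIC regression model: LIC[mg/g] = slope·R2*[Hz] + intercept.

    Attributes
    ----------
    slope : float
        mg/g per Hz, strictly positive.
    intercept : float
        mg/g.
    r2s_range_hz : tuple of float
        Validity range of the regression; inputs outside are still converted
        but flagged (gradient-echo relaxometry saturates at very high iron
        load, roughly LIC > 40 mg/g).
    source : str
        Provenance tag for reports.
    """

    slope: float
    intercept: float
    r2s_range_hz: tuple[float, float] = (0.0, 2000.0)
    source: str = "user"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")


#: Published linear regression of biopsy LIC on liver R2* at 1.5 T
#: (Hankins et al.): LIC[mg/g] = 0.0254·R2*[Hz] + 0.202.
HANKINS_CALIBRATION = LinearR2sCalibration(
    slope=0.0254, intercept=0.202, r2s_range_hz=(0.0, 1800.0), source="hankins"
)


def lic_from_r2s(
    r2star_hz: float, calib: LinearR2sCalibration = HANKINS_CALIBRATION
) -> tuple[float, bool]:
    """Estimate LIC (mg/g dry weight) from an R2* value.

    Returns
    -------
    (lic_mg_g, in_range) : tuple
        The linear estimate, clipped at 0 mg/g, and a flag that is False when
        R2* fell outside the calibration's validity range or the raw estimate
        was negative.
    """
    lo, hi = calib.r2s_range_hz
    in_range = bool(lo <= r2star_hz <= hi)
    lic = calib.slope * r2star_hz + calib.intercept
    if lic < 0:
        return 0.0, False
    return float(lic), in_range


def r2s_from_lic(
    lic_mg_g: float, calib: LinearR2sCalibration = HANKINS_CALIBRATION
) -> float:
    """Invert the linear calibration: R2*[Hz] = (LIC − intercept)/slope."""
    return (lic_mg_g - calib.intercept) / calib.slope


#: Category cut points, mg/g dry weight: ≤2 normal, (2, 15] elevated, >15 high.
DEFAULT_OVERLOAD_THRESHOLDS = (2.0, 15.0)


def classify_overload(
    lic_mg_g: float, thresholds: tuple[float, float] = DEFAULT_OVERLOAD_THRESHOLDS
) -> str:
    """Classify a LIC (mg/g) as ``normal``, ``elevated`` or ``high``.

    Boundaries are inclusive on the lower category: 2.0 mg/g is the maximum
    *normal* value, so it classifies as normal.
    """
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must be sorted ascending")
    if lic_mg_g <= lo:
        return "normal"
    if lic_mg_g <= hi:
        return "elevated"
    return "high"
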