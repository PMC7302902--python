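"""MOLLI T1 fitting: three-parameter recovery, polarity restoration,
Look-Locker correction, and the six-ROI liver averaging scheme.

The Look-Locker experiment samples an apparent recovery
``S(TI) = A − B·exp(−TI/T1*)`` whose rate is accelerated by the repeated
readouts; the tissue T1 is recovered by the standard correction
``T1 = T1*·(B/A − 1)``.  Scanner output is magnitude-only, so the sign of
the early (pre-null) samples is lost and must be restored before fitting:
we exhaustively try flipping the first k points (k = 0..n/2) and keep the
split with the lowest residual sum of squares.

Iron shortens T1, so the reciprocal R1[Hz] = 1000/T1[ms] increases with
iron overload.  No validated R1→LIC conversion exists; this module reports
T1/R1 only.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IRSeries",
    "T1Fit",
    "CircularROI",
    "ROISchemeT1",
    "fit_molli",
    "r1_from_t1",
    "t1_from_r1",
    "t1_roi_summary",
]


@dataclass(frozen=True)
class IRSeries:
    """Inversion times and signals for one ROI/voxel.

    ``polarity_restored`` is False for raw magnitude data (all signals
    non-negative, early-TI sign lost) and True for signed data.
    """

    ti_ms: tuple[float, ...]
    si: tuple[float, ...]
    polarity_restored: bool = False

    def __post_init__(self) -> None:
        ti = np.asarray(self.ti_ms, dtype=float)
        si = np.asarray(self.si, dtype=float)
        if ti.size != si.size:
            raise ValueError("ti_ms and si must have equal length")
        if ti.size < 4:
            raise ValueError("a 3-parameter fit needs at least 4 points")
        order = np.argsort(ti)
        object.__setattr__(self, "ti_ms", tuple(ti[order]))
        object.__setattr__(self, "si", tuple(si[order]))


@dataclass(frozen=True)
class T1Fit:
    """Three-parameter MOLLI fit with Look-Locker-corrected T1."""

    a_coeff: float
    b_coeff: float
    t1star_ms: float
    t1_ms: float
    r1_hz: float
    fit_rss: float
    polarity_split: int
    valid: bool = True


def r1_from_t1(t1_ms):
    """R1[Hz] = 1000 / T1[ms]."""
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("T1 must be strictly positive")
    out = 1000.0 / t1
    return float(out) if out.ndim == 0 else out


def t1_from_r1(r1_hz):
    """T1[ms] = 1000 / R1[Hz] (exact inverse of :func:`r1_from_t1`)."""
    r1 = np.asarray(r1_hz, dtype=float)
    if np.any(r1 <= 0):
        raise ValueError("R1 must be strictly positive")
    out = 1000.0 / r1
    return float(out) if out.ndim == 0 else out


def _fit_signed(ti: np.ndarray, si: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares fit of A − B·exp(−TI/T1*) to signed data.

    Returns (A, B, T1*, RSS); raises RuntimeError when the solver fails.
    """
    a0 = float(si[np.argmax(ti)])
    b0 = float(a0 - si[np.argmin(ti)])
    if b0 <= 0:
        b0 = max(abs(a0), 1.0)
    # crude rate guess from the TI span
    t1s0 = float(np.clip((ti.max() - ti.min()) / 3.0, 10.0, 5000.0))
    with np.errstate(over="ignore"):  # solver may probe tiny T1* transiently
        popt, _ = curve_fit(
            lambda t, a, b, t1s: a - b * np.exp(-t / t1s),
            ti,
            si,
            p0=(a0 if a0 != 0 else 1.0, b0, t1s0),
            maxfev=5000,
        )
    a, b, t1s = map(float, popt)
    rss = float(np.sum((si - (a - b * np.exp(-ti / t1s))) ** 2))
    return a, b, t1s, rss


def fit_molli(series: IRSeries, raise_on_invalid: bool = False) -> T1Fit:
    """Fit the MOLLI model and apply the Look-Locker correction.

    For magnitude input every polarity split k = 0..n//2 is tried (sign of
    the first k samples flipped); the split with the smallest residual sum
    of squares wins.  The corrected T1 = T1*·(B/A − 1); fits with B/A ≤ 1
    or non-positive T1* are flagged non-physical (``valid=False``) with
    NaN T1/R1.
    """
    ti = np.asarray(series.ti_ms)
    si = np.asarray(series.si, dtype=float)
    if np.allclose(si, si[0]):
        if raise_on_invalid:
            raise ValueError("all-equal signals: recovery unidentifiable")
        return T1Fit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 0, valid=False)

    splits = [0] if series.polarity_restored else range(0, len(si) // 2 + 1)
    best = None
    for k in splits:
        signed = si.copy()
        signed[:k] *= -1.0
        try:
            a, b, t1s, rss = _fit_signed(ti, signed)
        except RuntimeError:
            continue
        if best is None or rss < best[3]:
            best = (a, b, t1s, rss, k)
    if best is None:
        if raise_on_invalid:
            raise ValueError("MOLLI fit failed for every polarity split")
        return T1Fit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 0, valid=False)

    a, b, t1s, rss, k = best
    physical = a > 0 and t1s > 0 and (b / a) > 1.0
    if not physical:
        if raise_on_invalid:
            raise ValueError("non-physical MOLLI fit (B/A <= 1 or T1* <= 0)")
        return T1Fit(a, b, t1s, np.nan, np.nan, rss, k, valid=False)
    t1 = t1s * (b / a - 1.0)
    return T1Fit(a, b, t1s, t1, r1_from_t1(t1), rss, k, valid=True)


# --------------------------------------------------------------------------
# six-ROI averaging scheme


@dataclass(frozen=True)
class CircularROI:
    """Circular ROI in pixel coordinates with a liver-lobe tag."""

    center: tuple[float, float]  # (row, col)
    radius_px: float
    lobe: str  # "right" | "left"

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius_px**2


@dataclass(frozen=True)
class ROISchemeT1:
    """Six circular liver ROIs: four in the right lobe, two in the left.

    Each ROI's area must fall in [1, 3] cm² given the pixel size.
    """

    rois: tuple[CircularROI, ...]
    pixel_size_mm: tuple[float, float]
    area_bounds_cm2: tuple[float, float] = (1.0, 3.0)

    def __post_init__(self) -> None:
        lobes = [r.lobe for r in self.rois]
        if len(self.rois) != 6 or lobes.count("right") != 4 or lobes.count("left") != 2:
            raise ValueError("scheme requires six ROIs: four right-lobe, two left-lobe")
        px_cm2 = (self.pixel_size_mm[0] / 10.0) * (self.pixel_size_mm[1] / 10.0)
        for r in self.rois:
            area = np.pi * r.radius_px**2 * px_cm2
            lo, hi = self.area_bounds_cm2
            if not lo <= area <= hi:
                raise ValueError(
                    f"ROI area {area:.2f} cm2 outside [{lo}, {hi}] cm2 (radius {r.radius_px} px)"
                )


def t1_roi_summary(
    t1_map: np.ndarray,
    scheme: ROISchemeT1,
    liver_mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Arithmetic mean of the six ROI mean T1 values, and the derived R1.

    R1 is computed from the averaged T1 (1000/mean(T1)), matching the
    protocol of averaging T1 ROIs first and transforming once.  ROIs falling
    outside the liver mask are excluded with a warning; NaN pixels are
    ignored inside each ROI.
    """
    means = []
    for roi in scheme.rois:
        m = roi.mask(t1_map.shape)
        if liver_mask is not None and not np.all(m <= liver_mask):
            warnings.warn(f"ROI at {roi.center} extends outside the liver; excluded")
            continue
        vals = t1_map[m]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(f"ROI at {roi.center} has no valid pixels; excluded")
            continue
        means.append(float(vals.mean()))
    if not means:
        raise ValueError("no usable ROI in scheme")
    mean_t1 = float(np.mean(means))
    return mean_t1, r1_from_t1(mean_t1)
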