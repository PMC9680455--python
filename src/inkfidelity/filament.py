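"""Filament-deformation measurements from side-view images and time series.

Extracts the two support deflection angles, the mid-span diameter, the
time for each angle to flatten, and the diameter-shrink slope — the
observables of the suspended-filament collapse test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import (
    DomainError,
    InsufficientDataError,
    InvalidParameterError,
    SegmentationError,
)

__all__ = [
    "DeflectionObservation",
    "angle_fit_windows",
    "FilamentMask",
    "SeriesSummary",
    "segment_filament",
    "measure_deflection_angles",
    "measure_diameter",
    "time_to_flat",
    "diameter_slope",
    "NOT_REACHED",
    "DEFAULT_FLAT_THRESHOLD_DEG",
]

#: sentinel for an angle that never crosses the flat threshold
NOT_REACHED = float("inf")

#: pixel quantisation makes an exact 0° unattainable; this threshold is
#: recorded alongside any reported flattening time
DEFAULT_FLAT_THRESHOLD_DEG = 0.5

PAPER_GAPS_MM = (1.0, 2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class DeflectionObservation:
    """One time point of the filament collapse test."""

    t: float  # seconds since deposition
    theta1: float  # degrees, left support
    theta2: float  # degrees, right support
    diameter: float  # mm, at mid-span
    temperature_label: str = "RT_25C"  # RT_25C | INC_37C
    gap: float = 4.0  # mm

    def __post_init__(self) -> None:
        if self.t < 0:
            raise InvalidParameterError("t must be >= 0")
        for th in (self.theta1, self.theta2):
            if not (0 <= th < 90):
                raise InvalidParameterError(f"angles must be in [0, 90), got {th}")
        if not self.diameter > 0:
            raise InvalidParameterError("diameter must be > 0")
        if not self.gap > 0:
            raise InvalidParameterError("gap must be > 0")


@dataclass
class FilamentMask:
    """Binary filament mask with calibration and support locations.

    ``weights`` optionally carries the continuous filament-contrast signal
    (0..1 coverage) so midline centroids can be computed with sub-pixel
    precision; anti-aliased boundary pixels fall outside the binary mask
    but still carry coverage information.
    """

    mask: np.ndarray  # bool, True on the filament
    calibration: float  # px per mm
    supports: tuple  # (x_left, x_right) column indices
    weights: np.ndarray | None = None  # same shape, 0..1 coverage

    def __post_init__(self) -> None:
        if not self.calibration > 0:
            raise InvalidParameterError("calibration must be > 0")
        xl, xr = self.supports
        if not 0 <= xl < xr < self.mask.shape[1]:
            raise InvalidParameterError(f"bad support positions {self.supports}")


def segment_filament(
    image: np.ndarray,
    calibration: float,
    supports: tuple | None = None,
    bright_filament: bool = False,
) -> FilamentMask:
    """Segment the filament from a side-view frame.

    RGB frames are reduced to a red-minus-green contrast (the filament is
    dyed red); grayscale frames are Otsu-thresholded assuming a dark
    filament on a light background (``bright_filament`` flips polarity).
    The largest connected component is kept and must span at least half
    of the image width.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        signal = img[..., 0].astype(float) - img[..., 1].astype(float)
        polarity_high = True
    elif img.ndim == 2:
        signal = img.astype(float)
        polarity_high = bright_filament
    else:
        raise InvalidParameterError(f"expected 2-D or RGB image, got shape {img.shape}")
    if np.ptp(signal) == 0:
        raise SegmentationError("flat image: no filament found")
    thr = threshold_otsu(signal)
    fg = signal > thr if polarity_high else signal < thr
    labels, n = ndi.label(fg, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        raise SegmentationError("no foreground component found")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    cols = np.nonzero(mask.any(axis=0))[0]
    if len(cols) < 0.5 * img.shape[1]:
        raise SegmentationError(
            f"largest component spans {len(cols)} of {img.shape[1]} columns (< 50%)"
        )
    if supports is None:
        supports = (int(cols[0]), int(cols[-1]))
    # sub-pixel coverage weights: linear contrast between the background and
    # filament medians, clipped to [0, 1]; polarity-adjusted so 1 = filament
    fg_level = np.median(signal[mask])
    bg_level = np.median(signal[~mask])
    if polarity_high:
        weights = (signal - bg_level) / (fg_level - bg_level)
    else:
        weights = (bg_level - signal) / (bg_level - fg_level)
    weights = np.clip(weights, 0.0, 1.0)
    # restrict to the filament's neighbourhood so stray image content
    # cannot pull the centroid
    near = ndi.binary_dilation(mask, iterations=3)
    weights[~near] = 0.0
    return FilamentMask(mask=mask, calibration=calibration, supports=supports, weights=weights)


def _midline(fm: FilamentMask) -> tuple[np.ndarray, np.ndarray]:
    """Column positions and vertical centroid of the filament between supports.

    Uses the continuous coverage weights when available (sub-pixel), the
    binary mask otherwise.
    """
    xl, xr = fm.supports
    src = fm.weights if fm.weights is not None else fm.mask.astype(float)
    sub = src[:, xl : xr + 1]
    counts = sub.sum(axis=0)
    have = counts > 0
    rows = np.arange(fm.mask.shape[0], dtype=float)
    ysum = (sub * rows[:, None]).sum(axis=0)
    xs = np.arange(xl, xr + 1, dtype=float)[have]
    ys = ysum[have] / counts[have]
    return xs, ys


def _estimate_thickness_px(fm: FilamentMask) -> float:
    """Median vertical pixel count over the central half of the span."""
    xl, xr = fm.supports
    lo = xl + (xr - xl) // 4
    hi = xl + 3 * (xr - xl) // 4
    counts = fm.mask[:, lo : hi + 1].sum(axis=0)
    counts = counts[counts > 0]
    return float(np.median(counts)) if len(counts) else 1.0


def angle_fit_windows(
    fm: FilamentMask, fit_fraction: float = 0.1, inset: int | None = None
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Span-fraction windows used for the two support-angle line fits.

    The window starts ``inset`` pixels inside each support (by default
    half the filament thickness plus 2 px, past the rounded stroke end
    where the midline centroid is biased) and covers ``fit_fraction`` of
    the span, at least 10 px.  Returned as ``((lo1, hi1), (lo2, hi2))``
    fractions measured from the left support, so a model-side prediction
    can fit the analytic profile over the same physical windows.
    """
    xs, _ = _midline(fm)
    span = len(xs)
    if inset is None:
        inset = int(math.ceil(_estimate_thickness_px(fm) / 2.0)) + 2
    win = max(10, int(round(fit_fraction * span)))
    if span < 2 * (inset + win):
        raise InsufficientDataError(
            f"midline of {span} px too short for two {win}-px fit windows "
            f"with {inset}-px insets"
        )
    lo, hi = inset / span, (inset + win) / span
    return (lo, hi), (1.0 - hi, 1.0 - lo)


def measure_deflection_angles(
    fm: FilamentMask, fit_fraction: float = 0.1, inset: int | None = None
) -> tuple[float, float]:
    """Deflection angles (degrees from horizontal) at the two supports.

    A straight line is fitted to the filament midline over a window of
    ``fit_fraction`` of the span (at least 10 px) adjacent to each
    support; the angle is the magnitude of the fitted slope.  See
    :func:`angle_fit_windows` for the window geometry.
    """
    xs, ys = _midline(fm)
    span = len(xs)
    (lo1, hi1), (lo2, hi2) = angle_fit_windows(fm, fit_fraction, inset)
    i0, i1 = int(round(lo1 * span)), int(round(hi1 * span))
    j0, j1 = int(round(lo2 * span)), int(round(hi2 * span))
    s1 = np.polyfit(xs[i0:i1], ys[i0:i1], 1)[0]
    s2 = np.polyfit(xs[j0:j1], ys[j0:j1], 1)[0]
    return (
        float(np.degrees(np.arctan(abs(s1)))),
        float(np.degrees(np.arctan(abs(s2)))),
    )


def measure_diameter(fm: FilamentMask, at: float = 0.5, window_px: int = 5) -> float:
    """Filament thickness (mm) perpendicular to the midline at a span fraction.

    The vertical pixel extent at the requested column is projected onto
    the normal of the local midline direction.
    """
    if not 0 <= at <= 1:
        raise DomainError(f"span fraction must be in [0, 1], got {at}")
    xs, ys = _midline(fm)
    xl, xr = fm.supports
    x_target = xl + at * (xr - xl)
    i = int(np.argmin(np.abs(xs - x_target)))
    col = int(xs[i])
    vertical = int(fm.mask[:, col].sum())
    if vertical == 0:
        raise DomainError(f"no filament pixels at span fraction {at}")
    lo, hi = max(0, i - window_px), min(len(xs), i + window_px + 1)
    slope = np.polyfit(xs[lo:hi], ys[lo:hi], 1)[0] if hi - lo >= 2 else 0.0
    thickness_px = vertical * np.cos(np.arctan(slope))
    return float(thickness_px / fm.calibration)


def _first_crossing(t_min: np.ndarray, angles: np.ndarray, threshold: float) -> float:
    """Linear-interpolated first time an angle drops below threshold, minutes."""
    below = angles < threshold
    if below[0]:
        return 0.0
    idx = np.nonzero(below)[0]
    if len(idx) == 0:
        return NOT_REACHED
    i = idx[0]
    t0, t1 = t_min[i - 1], t_min[i]
    a0, a1 = angles[i - 1], angles[i]
    if a0 == a1:
        return float(t1)
    return float(t0 + (a0 - threshold) * (t1 - t0) / (a0 - a1))


def time_to_flat(
    series: list[DeflectionObservation],
    angle_threshold: float = DEFAULT_FLAT_THRESHOLD_DEG,
) -> tuple[float, float]:
    """Minutes until each deflection angle first falls below the threshold.

    Crossing times are linearly interpolated between bracketing frames;
    an angle that never crosses is reported as ``NOT_REACHED`` (inf).
    """
    if len(series) < 2:
        raise InsufficientDataError("need at least two observations")
    t = np.array([o.t for o in series], dtype=float)
    if np.any(np.diff(t) < 0):
        raise InvalidParameterError("series must be sorted by time")
    t_min = t / 60.0
    th1 = np.array([o.theta1 for o in series])
    th2 = np.array([o.theta2 for o in series])
    return (
        _first_crossing(t_min, th1, angle_threshold),
        _first_crossing(t_min, th2, angle_threshold),
    )


def diameter_slope(series: list[DeflectionObservation]) -> float:
    """Magnitude of the OLS diameter-vs-time slope, mm/min.

    Shrinkage is reported as a positive number.
    """
    if len(series) < 2:
        raise InsufficientDataError("need at least two observations")
    t_min = np.array([o.t for o in series], dtype=float) / 60.0
    d = np.array([o.diameter for o in series], dtype=float)
    if np.ptp(t_min) == 0:
        raise InsufficientDataError("all observations at the same time")
    slope = np.polyfit(t_min, d, 1)[0]
    return float(abs(slope))


@dataclass(frozen=True)
class SeriesSummary:
    """Headline numbers of one filament time series."""

    time_to_flat_theta1: float  # minutes, NOT_REACHED if never flat
    time_to_flat_theta2: float
    diameter_slope: float  # mm/min, positive magnitude
    n_frames: int
    flat_threshold_deg: float = DEFAULT_FLAT_THRESHOLD_DEG


def summarize_series(
    series: list[DeflectionObservation],
    angle_threshold: float = DEFAULT_FLAT_THRESHOLD_DEG,
) -> SeriesSummary:
    t1, t2 = time_to_flat(series, angle_threshold)
    return SeriesSummary(
        time_to_flat_theta1=t1,
        time_to_flat_theta2=t2,
        diameter_slope=diameter_slope(series),
        n_frames=len(series),
        flat_threshold_deg=angle_threshold,
    )
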