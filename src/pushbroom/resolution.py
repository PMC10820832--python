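"""Spectral- and spatial-resolution characterization.

Spatial resolution is assessed with a bar-target chart: per group of bars
the modulation contrast C = (Imax - Imin)/(Imax + Imin) is computed from
the detected intensity extrema, and the resolution is quoted as the bar
period at which C crosses 0.5. Linearity of the spatial sampling is the
residual of a straight-line fit of peak spacing (px) against bar period
(cm). Spectral resolution is the FWHM of an isolated emission line,
measured above a local baseline with linear interpolation of the
half-height crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .simulate import Spectrum

__all__ = [
    "IntensityProfile",
    "GroupContrast",
    "ContrastReport",
    "FwhmResult",
    "contrast",
    "analyze_line_pattern",
    "spacing_linearity",
    "spectral_resolution",
]


@dataclass
class IntensityProfile:
    """Intensity against pixel position along one axis of the frame."""

    positions_px: np.ndarray
    intensities: np.ndarray
    axis_label: str = "spatial"

    def __post_init__(self) -> None:
        self.positions_px = np.asarray(self.positions_px, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions_px.shape != self.intensities.shape:
            raise ValueError("positions and intensities must have equal length")
        if np.any(np.diff(self.positions_px) <= 0):
            raise ValueError("positions must be strictly ascending")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.axis_label not in ("spatial", "spectral"):
            raise ValueError("axis_label must be 'spatial' or 'spectral'")


@dataclass(frozen=True)
class GroupContrast:
    pattern_period_cm: float
    spatial_frequency_per_cm: float
    i_max: float
    i_min: float
    contrast: float
    resolved: bool


@dataclass
class ContrastReport:
    groups: list[GroupContrast]
    resolution_at_half_contrast_cm: float = float("nan")


@dataclass(frozen=True)
class FwhmResult:
    fwhm_nm: float
    peak_nm: float
    isolated: bool = True


def contrast(i_max: float, i_min: float) -> float:
    """Modulation contrast C = (Imax - Imin)/(Imax + Imin)."""
    if not (i_max >= i_min >= 0.0):
        raise ValueError("need Imax >= Imin >= 0")
    if i_max == 0.0:
        raise ValueError("contrast undefined for an all-zero signal")
    return (i_max - i_min) / (i_max + i_min)


def _group_extrema(y: np.ndarray) -> tuple[float, float, bool]:
    """(Imax, Imin, resolved) of one bar group.

    Imax is the mean of detected local maxima, Imin the mean of the local
    minima lying between them. A group with fewer than 2 maxima is
    unresolved (single merged peak).
    """
    span = float(np.ptp(y))
    if span == 0:
        return float(y.max()), float(y.min()), False
    peaks, _ = find_peaks(y, prominence=0.05 * span)
    if peaks.size < 2:
        return float(y.max()), float(y.min()), False
    troughs, _ = find_peaks(-y, prominence=0.05 * span)
    troughs = troughs[(troughs > peaks.min()) & (troughs < peaks.max())]
    if troughs.size == 0:
        return float(y.max()), float(y.min()), False
    return float(y[peaks].mean()), float(y[troughs].mean()), True


def analyze_line_pattern(
    profile: IntensityProfile,
    group_boundaries: Sequence[tuple[int, int]],
    period_cm: Sequence[float],
) -> ContrastReport:
    """Per-group bar contrast and the period at which C crosses 0.5.

    ``group_boundaries`` are [start, stop) pixel ranges in the profile's
    position coordinates; ``period_cm`` the bar-pair period of each group.
    Unresolved groups (a single merged intensity peak) are recorded with
    C = 0. The half-contrast resolution is obtained by piecewise-linear
    interpolation of C against period; NaN if C never crosses 0.5.
    """
    if len(group_boundaries) != len(period_cm):
        raise ValueError("one period per group required")
    if len(group_boundaries) < 2:
        raise ValueError("need at least 2 groups")
    pos = profile.positions_px
    groups: list[GroupContrast] = []
    for (start, stop), period in zip(group_boundaries, period_cm):
        sel = (pos >= start) & (pos < stop)
        if not np.any(sel):
            raise ValueError(f"empty group [{start}, {stop})")
        i_max, i_min, resolved = _group_extrema(profile.intensities[sel])
        c = contrast(i_max, i_min) if resolved else 0.0
        groups.append(GroupContrast(float(period), 1.0 / float(period),
                                    i_max, i_min, c, resolved))
    order = np.argsort([g.pattern_period_cm for g in groups])
    p = np.array([groups[i].pattern_period_cm for i in order])
    c = np.array([groups[i].contrast for i in order])
    res = float("nan")
    for k in range(len(p) - 1):
        c0, c1 = c[k], c[k + 1]
        if (c0 - 0.5) * (c1 - 0.5) <= 0 and c0 != c1:
            res = float(p[k] + (0.5 - c0) * (p[k + 1] - p[k]) / (c1 - c0))
            break
    return ContrastReport(groups=groups, resolution_at_half_contrast_cm=res)


def spacing_linearity(
    profile: IntensityProfile,
    group_boundaries: Sequence[tuple[int, int]],
    period_cm: Sequence[float],
) -> tuple[float, float, float]:
    """Straight-line fit of mean consecutive-maxima spacing vs bar period.

    Returns ``(slope_px_per_cm, intercept_px, max_abs_residual_px)``. A
    distortion-free sampling gives residuals at the sub-pixel level;
    geometric distortion shows up as large residuals.
    """
    pos, y = profile.positions_px, profile.intensities
    periods, spacings = [], []
    for (start, stop), period in zip(group_boundaries, period_cm):
        sel = (pos >= start) & (pos < stop)
        yy = y[sel]
        if yy.size == 0:
            continue
        span = float(np.ptp(yy))
        if span == 0:
            continue
        peaks, _ = find_peaks(yy, prominence=0.05 * span)
        if peaks.size < 2:
            continue
        periods.append(float(period))
        spacings.append(float(np.mean(np.diff(pos[sel][peaks]))))
    if len(set(periods)) < 3:
        raise ValueError("need measurable maxima spacings at >= 3 distinct periods")
    slope, intercept = np.polyfit(periods, spacings, 1)
    resid = np.asarray(spacings) - (slope * np.asarray(periods) + intercept)
    return float(slope), float(intercept), float(np.max(np.abs(resid)))


def spectral_resolution(
    spectrum: Spectrum | IntensityProfile,
    peak_near_nm: float,
    search_window_nm: float = 20.0,
    baseline_window_nm: float = 60.0,
) -> FwhmResult:
    """FWHM of an isolated emission line near ``peak_near_nm``.

    The baseline is the minimum within ``baseline_window_nm`` of the peak
    (lamp lines sit on a continuum); the width is measured between the
    linearly interpolated half-height crossings. If another comparable
    peak lies within twice the measured FWHM the result is flagged
    non-isolated rather than rejected.
    """
    if isinstance(spectrum, IntensityProfile):
        x, y = spectrum.positions_px, spectrum.intensities
    else:
        x, y = spectrum.wavelengths_nm, spectrum.intensities
    near = np.abs(x - peak_near_nm) <= search_window_nm
    if not np.any(near):
        raise ValueError("no samples near the requested peak position")
    i_pk = int(np.flatnonzero(near)[np.argmax(y[near])])
    if 0 < i_pk < x.size - 1 and (y[i_pk] < y[i_pk - 1] or y[i_pk] < y[i_pk + 1]):
        raise ValueError("no local maximum near the requested position")
    win = np.abs(x - x[i_pk]) <= baseline_window_nm
    baseline = float(y[win].min())
    half = baseline + 0.5 * (y[i_pk] - baseline)

    def crossing(direction: int) -> float:
        i = i_pk
        while 0 < i < x.size - 1 and y[i + direction] > half:
            i += direction
        j = i + direction
        if j < 0 or j >= x.size:
            raise ValueError("half-height crossing outside the sampled range")
        # linear interpolation between the bracketing samples
        return float(x[i] + (half - y[i]) * (x[j] - x[i]) / (y[j] - y[i]))

    left, right = crossing(-1), crossing(+1)
    fwhm = right - left
    # isolation check: another prominent peak within 2 FWHM of the line
    zone = (np.abs(x - x[i_pk]) <= 2.0 * fwhm) & (np.abs(x - x[i_pk]) > fwhm / 2.0)
    isolated = not np.any(y[zone] > half)
    return FwhmResult(fwhm_nm=float(fwhm), peak_nm=float(x[i_pk]), isolated=isolated)
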