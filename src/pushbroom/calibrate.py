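"""Wavelength-to-pixel calibration and smile correction.

The dispersion of the prism maps wavelength to sensor column through a
three-parameter monotone model derived from the one-term Sellmeier form,

    pixel(lambda) = A' + B' * sqrt(lambda^2 / (lambda^2 - C)),

fitted by nonlinear least squares to (known wavelength, measured pixel)
pairs extracted from emission-line frames. A fourth additive constant in
the raw relation is degenerate with A' and is fixed at zero. On top of the
column mapping, the spectral smile — a per-row horizontal shift of the
wavelength axis, quadratic in the normalized row coordinate — is estimated
from monochromatic frames and undone by remapping.

Column coordinates are 0-based with pixel centers at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .simulate import SmileModel, row_coordinate

__all__ = [
    "PeakEntry",
    "PeakTable",
    "CalibrationFit",
    "extract_peaks",
    "assign_wavelengths",
    "fit_dispersion",
    "wavelength_to_pixel",
    "pixel_to_wavelength",
    "estimate_smile",
    "remap_frame",
    "default_calibration",
]


@dataclass(frozen=True)
class PeakEntry:
    wavelength_nm: float | None
    pixel: float
    source: str = ""


@dataclass
class PeakTable:
    """Measured emission-line peaks: known wavelength vs sub-pixel column."""

    entries: list[PeakEntry]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([e.wavelength_nm for e in self.entries], dtype=float)

    @property
    def pixels(self) -> np.ndarray:
        return np.array([e.pixel for e in self.entries], dtype=float)


def _dispersion_term(lam: np.ndarray, C: float) -> np.ndarray:
    return np.sqrt(lam**2 / (lam**2 - C))


@dataclass
class CalibrationFit:
    """Fitted wavelength <-> pixel contract plus the smile map.

    ``A_prime``/``B_prime`` in pixels, ``C_disp`` in nm^2. The mapping is
    strictly monotone in wavelength over [lambda_min_nm, lambda_max_nm]
    as long as B' != 0 and C != 0.
    """

    A_prime: float
    B_prime: float
    C_disp: float
    residual_rms_px: float = 0.0
    smile: SmileModel = field(default_factory=SmileModel)
    lambda_min_nm: float = 300.0
    lambda_max_nm: float = 1000.0

    def __post_init__(self) -> None:
        if self.C_disp >= self.lambda_min_nm**2:
            raise ValueError("C_disp must be below the squared minimum wavelength")
        if self.B_prime == 0.0 or self.C_disp == 0.0:
            raise ValueError("degenerate (flat) wavelength map: B'=0 or C=0")
        if not np.isfinite(self.residual_rms_px):
            raise ValueError("residual RMS must be finite")

    # -- forward map ------------------------------------------------------
    def wavelength_to_pixel(self, lambda_nm):
        lam = np.asarray(lambda_nm, dtype=float)
        if np.any(lam < self.lambda_min_nm) or np.any(lam > self.lambda_max_nm):
            raise ValueError("wavelength outside the calibrated range")
        px = self.A_prime + self.B_prime * _dispersion_term(lam, self.C_disp)
        return px if px.ndim else float(px)

    # -- inverse map ------------------------------------------------------
    def pixel_to_wavelength(self, pixel, strict: bool = True):
        """Invert the dispersion map algebraically.

        With s = (pixel - A')/B', lambda = sqrt(C s^2 / (s^2 - 1)) for
        C > 0 (and the analogous branch for C < 0). With ``strict`` the
        result must lie inside the calibrated range; otherwise returns
        ``(lambda, valid_mask)`` with out-of-range entries flagged.
        """
        px = np.atleast_1d(np.asarray(pixel, dtype=float))
        p_lo = self.wavelength_to_pixel(self.lambda_min_nm)
        p_hi = self.wavelength_to_pixel(self.lambda_max_nm)
        lo, hi = min(p_lo, p_hi), max(p_lo, p_hi)
        valid = (px >= lo) & (px <= hi)
        s = (px - self.A_prime) / self.B_prime
        lam = np.full(px.shape, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            s2 = s[valid] ** 2
            lam[valid] = np.sqrt(self.C_disp * s2 / (s2 - 1.0))
        if strict:
            if not np.all(valid):
                raise ValueError("pixel outside the calibrated column range")
            out = lam if np.ndim(pixel) else float(lam[0])
            return out
        return lam, valid

    def is_monotone(self, n_grid: int = 701) -> bool:
        lam = np.linspace(self.lambda_min_nm, self.lambda_max_nm, n_grid)
        return bool(np.all(np.diff(self.wavelength_to_pixel(lam)) < 0)
                    or np.all(np.diff(self.wavelength_to_pixel(lam)) > 0))


def wavelength_to_pixel(lambda_nm, fit: CalibrationFit):
    """Fractional column of a wavelength under the fitted dispersion model."""
    return fit.wavelength_to_pixel(lambda_nm)


def pixel_to_wavelength(pixel, fit: CalibrationFit):
    """Wavelength at a fractional column (inverse of the dispersion model)."""
    return fit.pixel_to_wavelength(pixel)


def default_calibration(
    layout=None,
    C_disp: float | None = None,
    margin_px: float = 14.0,
    smile: SmileModel | None = None,
) -> CalibrationFit:
    """Ground-truth calibration used by the simulator.

    Solves A', B' so the layout wavelength range spans the spectral axis
    symmetrically, leaving ``margin_px`` columns at each end, with
    wavelength increasing along columns. ``C_disp`` defaults to the
    one-term Sellmeier C of the F2 prism glass, making the simulated
    dispersion curvature consistent with the optics model (strong in the
    blue, ~8-10 nm/px at the red end of the sensor).
    """
    from .optics import F2_SELLMEIER_C_NM2

    if C_disp is None:
        C_disp = F2_SELLMEIER_C_NM2
    from .optics import OpticalLayout

    layout = layout if layout is not None else OpticalLayout()
    lo, hi = layout.wavelength_range_nm
    s_lo = float(_dispersion_term(np.asarray(lo, float), C_disp))
    s_hi = float(_dispersion_term(np.asarray(hi, float), C_disp))
    p_lo, p_hi = margin_px, layout.sensor_cols - 1 - margin_px
    B = (p_hi - p_lo) / (s_hi - s_lo)
    A = p_lo - B * s_lo
    return CalibrationFit(A_prime=A, B_prime=B, C_disp=C_disp,
                          smile=smile if smile is not None else SmileModel(),
                          lambda_min_nm=lo, lambda_max_nm=hi)


def _parabolic_refine(profile: np.ndarray, i: int) -> float:
    """Three-point parabolic sub-pixel refinement of a local maximum."""
    if i <= 0 or i >= profile.size - 1:
        return float(i)
    y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(i)
    return float(i + 0.5 * (y0 - y2) / denom)


def extract_peaks(
    frame: np.ndarray,
    row_band: tuple[int, int],
    min_prominence: float = 10.0,
) -> PeakTable:
    """Sub-pixel peak columns of the mean spectral profile over a row band.

    Wavelengths are not known at this stage; attach them with
    :func:`assign_wavelengths`.
    """
    frame = np.asarray(frame, dtype=float)
    r0, r1 = row_band
    if not (0 <= r0 < r1 <= frame.shape[0]):
        raise ValueError("row band outside the frame")
    profile = frame[r0:r1].mean(axis=0)
    if np.ptp(profile) == 0:
        raise ValueError("frame is constant over the row band; no peaks")
    idx, _ = find_peaks(profile, prominence=min_prominence)
    if idx.size == 0:
        raise ValueError("no peak above the prominence threshold")
    entries = [PeakEntry(None, _parabolic_refine(profile, int(i))) for i in idx]
    entries.sort(key=lambda e: e.pixel)
    return PeakTable(entries)


def assign_wavelengths(
    table: PeakTable, wavelengths_nm, increasing: bool = True
) -> PeakTable:
    """Attach known source wavelengths to extracted peaks, in column order.

    ``increasing=True`` assumes wavelength grows with column (the default
    orientation of the simulator's truth mapping).
    """
    wls = sorted(float(w) for w in wavelengths_nm)
    if len(wls) != len(table):
        raise ValueError("wavelength count does not match peak count")
    if not increasing:
        wls = wls[::-1]
    return PeakTable([replace(e, wavelength_nm=w)
                      for e, w in zip(table.entries, wls)])


def fit_dispersion(
    peaks: PeakTable,
    smile: SmileModel | None = None,
    wavelength_range_nm: tuple[float, float] = (300.0, 1000.0),
    seed: int = 0,
) -> CalibrationFit:
    """Least-squares fit of the three-parameter dispersion model.

    Requires at least 4 peaks spanning at least 200 nm. Initialization:
    A' = mean(pixel), B' = -(pixel range), C = (250 nm)^2, with up to
    three jittered restarts on failure (fixed seed).
    """
    lam, px = peaks.wavelengths, peaks.pixels
    if np.any(~np.isfinite(lam)):
        raise ValueError("all peaks need known wavelengths for fitting")
    if len(peaks) < 4:
        raise ValueError("need at least 4 calibration peaks")
    if np.unique(lam).size != lam.size:
        raise ValueError("calibration wavelengths must be distinct")
    if np.ptp(lam) < 200.0:
        raise ValueError("calibration peaks must span at least 200 nm")

    def residual(p):
        A, B, C = p
        if C >= 0.98 * lam.min() ** 2:  # keep the model defined on the data
            C = 0.98 * lam.min() ** 2
        return A + B * _dispersion_term(lam, C) - px

    rng = np.random.default_rng(seed)
    x0 = np.array([px.mean(), -(np.ptp(px)), 250.0**2])
    best = None
    for attempt in range(4):
        start = x0 if attempt == 0 else x0 * rng.normal(1.0, 0.3, size=3)
        try:
            sol = least_squares(residual, start, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost < 1e3:
            break
    if best is None:
        raise RuntimeError("dispersion fit did not converge")
    A, B, C = best.x
    rms = float(np.sqrt(np.mean(residual(best.x) ** 2)))
    lo = max(wavelength_range_nm[0], np.sqrt(max(C, 0.0)) * 1.02)
    fit = CalibrationFit(A_prime=float(A), B_prime=float(B), C_disp=float(C),
                         residual_rms_px=rms,
                         smile=smile if smile is not None else SmileModel(),
                         lambda_min_nm=lo,
                         lambda_max_nm=wavelength_range_nm[1])
    if not fit.is_monotone():
        raise RuntimeError("fitted wavelength map is not monotone")
    return fit


def _row_peak_columns(
    frame: np.ndarray, min_height: float = 20.0
) -> tuple[np.ndarray, np.ndarray]:
    """Sub-pixel peak column per row of a monochromatic frame.

    Returns (row indices, columns) for rows whose peak rises ``min_height``
    counts above the row median.
    """
    frame = np.asarray(frame, dtype=float)
    rows, cols = [], []
    for r in range(frame.shape[0]):
        line = frame[r]
        i = int(np.argmax(line))
        if line[i] - np.median(line) < min_height:
            continue
        rows.append(r)
        cols.append(_parabolic_refine(line, i))
    return np.array(rows, dtype=int), np.array(cols, dtype=float)


def estimate_smile(
    frames, n_rows: int | None = None, min_height: float = 20.0,
    min_usable_rows: int = 10,
) -> SmileModel:
    """Quadratic smile model from one or more monochromatic frames.

    Per frame, per-row sub-pixel peak columns are fitted with a quadratic
    in the normalized row coordinate; the center-row shift is zero by
    construction, and the linear/quadratic coefficients are averaged over
    frames.
    """
    if hasattr(frames, "ndim"):
        frames = [frames]
    a1s, a2s = [], []
    for frame in frames:
        n = frame.shape[0] if n_rows is None else n_rows
        rows, cols = _row_peak_columns(frame, min_height=min_height)
        if rows.size < min_usable_rows:
            raise ValueError(
                f"only {rows.size} rows with a detectable peak (need "
                f">= {min_usable_rows})")
        u = row_coordinate(n)[rows]
        coeffs = np.polyfit(u, cols, 2)  # c2*u^2 + c1*u + c0
        a2s.append(coeffs[0])
        a1s.append(coeffs[1])
    return SmileModel(a1=float(np.mean(a1s)), a2=float(np.mean(a2s)))


def remap_frame(frame: np.ndarray, fit: CalibrationFit) -> np.ndarray:
    """Undo the smile: shift each row by minus its profile offset.

    Linear interpolation along the spectral axis; output is float64 so no
    quantization is added on top of the sensor's. A zero smile model makes
    this (numerically) the identity.
    """
    frame = np.asarray(frame, dtype=float)
    n_rows, n_cols = frame.shape
    shifts = fit.smile.row_shifts(n_rows)
    out = np.empty_like(frame)
    cols = np.arange(n_cols, dtype=float)
    for r in range(n_rows):
        out[r] = np.interp(cols + shifts[r], cols, frame[r])
    return out
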