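"""Synthetic push-broom frame generator.

Stands in for the physical camera: spectral sources (fluorescent-lamp
emission lines, laser diodes, daylight-like illumination), leaf and panel
reflectance models, and a renderer that projects a 1-D scene along the
slit through the dispersion mapping onto a 2-D detector frame — including
spectral smile, instrument line spread, Gaussian noise, and 8-bit (Mono8)
quantization.

Axis convention (configurable through :class:`~pushbroom.optics.OpticalLayout`):
rows are spatial positions along the slit (544 by default), columns are
the spectral axis (728 by default).

Leaf reflectance is parametric, not radiative-transfer based: a broad
green Gaussian peak near 550 nm, a chlorophyll absorption dip near
670 nm, and a logistic red edge rising to an NIR plateau past ~720 nm.
The two classes (lettuce-like "A", arugula-like "B") differ chiefly in
the distribution of the green-peak amplitude — with heavy overlap, so a
single-amplitude threshold cannot separate them — and more subtly in
red-edge position, green-peak width, and NIR level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

if TYPE_CHECKING:  # pragma: no cover
    from .calibrate import CalibrationFit
    from .optics import OpticalLayout

__all__ = [
    "DEFAULT_GRID_NM",
    "Spectrum",
    "SmileModel",
    "Strip",
    "Scene",
    "make_lamp_spectrum",
    "make_leaf_spectrum",
    "daylight_illumination",
    "flat_illumination",
    "render_frame",
    "simulate_scan",
    "make_leaf_dataset",
    "leaf_panel_scene",
    "line_pattern_scene",
    "DEFAULT_CALIBRATION_WAVELENGTHS",
]

#: Standard wavelength grid, 300-1000 nm at 1 nm.
DEFAULT_GRID_NM = np.arange(300.0, 1001.0, 1.0)

GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma -> FWHM factor

#: Default calibration sources: fluorescent-lamp lines, RGB laser diodes
#: (450/520/638 nm) and an IR diode (850 nm) — eight known wavelengths.
DEFAULT_CALIBRATION_WAVELENGTHS = (405.0, 436.0, 450.0, 520.0, 546.0, 577.0, 638.0, 850.0)


@dataclass
class Spectrum:
    """A sampled spectral curve on a strictly increasing wavelength grid."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths_nm.shape != self.intensities.shape:
            raise ValueError("wavelengths and intensities must have equal length")
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.size < 2:
            raise ValueError("spectrum needs a 1-D grid of at least 2 samples")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def __call__(self, lambda_nm) -> np.ndarray:
        """Linear interpolation; zero outside the sampled grid."""
        return np.interp(
            lambda_nm, self.wavelengths_nm, self.intensities, left=0.0, right=0.0
        )


@dataclass(frozen=True)
class SmileModel:
    """Per-row horizontal shift of the spectral axis (spectral smile).

    The shift is a polynomial in the normalized row coordinate
    u in [-1, 1] (u = 0 at the center row): shift(u) = a1*u + a2*u^2,
    zero at the frame center by construction.
    """

    a1: float = 0.0
    a2: float = 0.0

    @classmethod
    def quadratic(cls, max_shift_px: float) -> "SmileModel":
        """Pure quadratic smile with the given shift at the frame edges."""
        return cls(a1=0.0, a2=float(max_shift_px))

    @property
    def max_shift_px(self) -> float:
        u = np.linspace(-1.0, 1.0, 201)
        return float(np.max(np.abs(self.shift(u))))

    def shift(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        return self.a1 * u + self.a2 * u**2

    def row_shifts(self, n_rows: int) -> np.ndarray:
        u = row_coordinate(n_rows)
        return self.shift(u)


def row_coordinate(n_rows: int) -> np.ndarray:
    """Normalized row coordinate u in [-1, 1], 0 at the center row."""
    return 2.0 * (np.arange(n_rows) - (n_rows - 1) / 2.0) / (n_rows - 1)


@dataclass
class Strip:
    """One segment of the slit line: a material over a fraction of its extent.

    Materials: ``leaf_class_A``, ``leaf_class_B``, ``white_panel``,
    ``black_ground``, ``line_pattern`` (binary bars along the slit, params:
    ``period_cm``, ``rows_per_cm``, optional ``high``/``low``), ``custom``
    (params: ``wavelengths_nm``, ``values``).
    """

    extent: float
    material: str
    params: dict = field(default_factory=dict)


MATERIALS = ("leaf_class_A", "leaf_class_B", "white_panel", "black_ground",
             "line_pattern", "custom")


@dataclass
class Scene:
    """Ordered strips partitioning the slit line [0, 1]."""

    strips: list[Strip]

    def __post_init__(self) -> None:
        if not self.strips:
            raise ValueError("scene needs at least one strip")
        total = sum(s.extent for s in self.strips)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"strip extents must partition [0, 1]; sum={total}")
        for s in self.strips:
            if s.extent <= 0:
                raise ValueError("strip extents must be positive")
            if s.material not in MATERIALS:
                raise ValueError(f"unknown material {s.material!r}")

    def strip_of_row(self, row: int, n_rows: int) -> tuple[int, Strip]:
        """Strip index and strip containing the given spatial row."""
        edges = np.cumsum([s.extent for s in self.strips])
        frac = (row + 0.5) / n_rows
        idx = int(np.searchsorted(edges, frac))
        idx = min(idx, len(self.strips) - 1)
        return idx, self.strips[idx]

    def row_ranges(self, n_rows: int) -> list[tuple[int, int]]:
        """Half-open [start, stop) row range per strip."""
        edges = np.concatenate([[0.0], np.cumsum([s.extent for s in self.strips])])
        bounds = np.round(edges * n_rows).astype(int)
        return [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(self.strips))]


def make_lamp_spectrum(
    line_centers: Sequence[float],
    line_widths: Sequence[float] | float = 3.0,
    line_heights: Sequence[float] | float = 1.0,
    continuum: float = 0.0,
    grid_nm: np.ndarray | None = None,
) -> Spectrum:
    """Emission-line source: Gaussian lines (FWHM widths) plus a continuum."""
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
    centers = np.atleast_1d(np.asarray(line_centers, dtype=float))
    if centers.size and (centers.min() < 300.0 or centers.max() > 1000.0):
        raise ValueError("line centers must lie within 300-1000 nm")
    widths = np.broadcast_to(np.asarray(line_widths, dtype=float), centers.shape)
    heights = np.broadcast_to(np.asarray(line_heights, dtype=float), centers.shape)
    y = np.full(grid.shape, float(continuum))
    for c, w, h in zip(centers, widths, heights):
        sigma = w / GAUSS_FWHM
        y = y + h * np.exp(-0.5 * ((grid - c) / sigma) ** 2)
    return Spectrum(grid, y)


# Class-conditional leaf parameters: mean/sd of green-peak amplitude and
# width, NIR plateau level, and red-edge inflection (nm). Chosen so the
# amplitude distributions overlap strongly while the joint spectral shape
# remains separable.
_LEAF_CLASSES = {
    "A": dict(g_amp=(0.30, 0.05), g_sig=(36.0, 2.0), nir=(0.54, 0.035),
              edge=(711.0, 2.5), edge_width=12.0),
    "B": dict(g_amp=(0.22, 0.05), g_sig=(43.0, 2.0), nir=(0.63, 0.035),
              edge=(723.0, 2.5), edge_width=14.0),
}
_LEAF_ALIASES = {"A": "A", "B": "B", "lettuce": "A", "arugula": "B",
                 "leaf_class_A": "A", "leaf_class_B": "B"}


def make_leaf_spectrum(
    class_id: str,
    rng_seed: int | np.random.Generator = 0,
    amplitude_jitter: float = 0.15,
    angle_jitter: float = 0.5,
    grid_nm: np.ndarray | None = None,
) -> Spectrum:
    """Draw one leaf reflectance spectrum for class ``A`` (lettuce-like) or
    ``B`` (arugula-like).

    ``amplitude_jitter`` scales a multiplicative Gaussian brightness factor
    (leaf-to-leaf albedo variation); ``angle_jitter`` scales a random
    foreshortening factor cos(theta), theta uniform in [0, angle_jitter*60 deg]
    (viewing/illumination angle variation). Both multiply the whole
    spectrum, so absolute amplitudes are unreliable class cues while band
    ratios are preserved.
    """
    if class_id not in _LEAF_ALIASES:
        raise ValueError(f"unknown leaf class {class_id!r}")
    if not (0.0 <= amplitude_jitter < 1.0 and 0.0 <= angle_jitter < 1.0):
        raise ValueError("jitters must lie in [0, 1)")
    p = _LEAF_CLASSES[_LEAF_ALIASES[class_id]]
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)

    g_amp = rng.normal(*p["g_amp"])
    g_sig = rng.normal(*p["g_sig"])
    nir = rng.normal(*p["nir"])
    edge = rng.normal(*p["edge"])

    base = 0.04 + 0.015 * np.exp(-(((grid - 450.0) / 60.0) ** 2))
    green = g_amp * np.exp(-0.5 * ((grid - 550.0) / g_sig) ** 2)
    red_edge = nir / (1.0 + np.exp(-(grid - edge) / p["edge_width"]))
    chl_dip = 0.03 * np.exp(-0.5 * ((grid - 670.0) / 18.0) ** 2)
    refl = base + green + red_edge - chl_dip

    scale = 1.0 + amplitude_jitter * float(np.clip(rng.normal(), -2.5, 2.5))
    scale *= math.cos(angle_jitter * rng.uniform(0.0, 1.0) * math.pi / 3.0)
    refl = refl * scale
    # smooth multiplicative speckle (surface texture)
    speckle = np.convolve(rng.normal(size=grid.size), np.ones(15) / 15.0, mode="same")
    refl = refl * (1.0 + 0.01 * speckle)
    return Spectrum(grid, np.clip(refl, 0.0, 1.0))


def daylight_illumination(
    amplitude: float = 1.0, grid_nm: np.ndarray | None = None
) -> Spectrum:
    """Smooth daylight-like illumination: 5800 K Planck curve, peak-normalized."""
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
    lam_m = grid * 1e-9
    hc_kT = 6.62607015e-34 * 2.99792458e8 / (1.380649e-23 * 5800.0)
    planck = lam_m**-5 / np.expm1(hc_kT / lam_m)
    return Spectrum(grid, amplitude * planck / planck.max())


def flat_illumination(
    amplitude: float = 1.0, grid_nm: np.ndarray | None = None
) -> Spectrum:
    grid = DEFAULT_GRID_NM if grid_nm is None else np.asarray(grid_nm, dtype=float)
    return Spectrum(grid, np.full(grid.shape, float(amplitude)))


def _strip_reflectance(
    strip: Strip, row: int, strip_start: int, rng: np.random.Generator,
) -> Spectrum | float:
    """Reflectance of one spatial row: a Spectrum, or a scalar for flat materials."""
    m, prm = strip.material, strip.params
    if m == "white_panel":
        return float(prm.get("reflectance", 1.0))
    if m == "black_ground":
        return float(prm.get("reflectance", 0.03))
    if m in ("leaf_class_A", "leaf_class_B"):
        return make_leaf_spectrum(
            "A" if m.endswith("A") else "B",
            rng,
            amplitude_jitter=float(prm.get("amplitude_jitter", 0.15)),
            angle_jitter=float(prm.get("angle_jitter", 0.5)),
        )
    if m == "custom":
        if "spectrum" in prm:
            return prm["spectrum"]
        return Spectrum(np.asarray(prm["wavelengths_nm"], float),
                        np.asarray(prm["values"], float))
    if m == "line_pattern":
        period_rows = float(prm["period_cm"]) * float(prm["rows_per_cm"])
        if period_rows <= 0:
            raise ValueError("line pattern period must be positive")
        bar = period_rows / 2.0  # one bright + one dark bar per period
        k = int((row - strip_start + float(prm.get("phase_rows", 0.0))) // bar)
        return float(prm.get("high", 0.95)) if k % 2 == 0 else float(prm.get("low", 0.02))
    raise ValueError(f"unknown material {m!r}")  # pragma: no cover


def render_frame(
    scene: Scene,
    illumination: Spectrum,
    layout: "OpticalLayout",
    calib_truth: "CalibrationFit",
    smile: SmileModel | None = None,
    noise_sd: float = 2.0,
    rng_seed: int | np.random.Generator = 0,
    lsf_fwhm_px: float = 6.0,
    spatial_lsf_fwhm_px: float = 3.0,
    exposure: float = 200.0,
    dialect: str = "mono8",
) -> np.ndarray:
    """Render one detector frame (rows = spatial, columns = spectral).

    For each spatial row the at-sensor radiance (material reflectance x
    illumination) is sampled at the wavelength that the truth calibration
    assigns to each column, shifted by the smile profile, convolved with a
    Gaussian instrument line spread (``lsf_fwhm_px`` along the spectral
    axis, ``spatial_lsf_fwhm_px`` across rows), scaled by ``exposure``,
    and finally Gaussian noise of ``noise_sd`` counts is added before
    clipping to [0, 255]. ``dialect='mono8'`` quantizes to uint8 (the
    camera's Mono8 format); ``dialect='float'`` skips quantization.
    """
    if dialect not in ("mono8", "float"):
        raise ValueError("dialect must be 'mono8' or 'float'")
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    n_rows, n_cols = layout.sensor_rows, layout.sensor_cols
    lo, hi = layout.wavelength_range_nm
    if not (calib_truth.lambda_min_nm <= lo and calib_truth.lambda_max_nm >= hi):
        raise ValueError("calibration does not cover the layout wavelength range")

    cols = np.arange(n_cols, dtype=float)
    shifts = smile.row_shifts(n_rows) if smile is not None else np.zeros(n_rows)
    ranges = scene.row_ranges(n_rows)

    frame = np.zeros((n_rows, n_cols), dtype=float)
    illum_cache: dict[float, np.ndarray] = {}
    for (start, stop), strip in zip(ranges, scene.strips):
        for row in range(start, stop):
            refl = _strip_reflectance(strip, row, start, rng)
            eff = cols - shifts[row]
            lam, valid = calib_truth.pixel_to_wavelength(eff, strict=False)
            radiance = np.zeros(n_cols)
            if np.isscalar(refl) or isinstance(refl, float):
                radiance[valid] = float(refl) * illumination(lam[valid])
            else:
                radiance[valid] = refl(lam[valid]) * illumination(lam[valid])
            frame[row] = radiance

    if lsf_fwhm_px > 0:
        frame = gaussian_filter1d(frame, lsf_fwhm_px / GAUSS_FWHM, axis=1,
                                  mode="nearest")
    if spatial_lsf_fwhm_px > 0:
        frame = gaussian_filter1d(frame, spatial_lsf_fwhm_px / GAUSS_FWHM, axis=0,
                                  mode="nearest")
    frame = frame * exposure
    if noise_sd > 0:
        frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
    frame = np.clip(frame, 0.0, 255.0)
    return np.round(frame).astype(np.uint8) if dialect == "mono8" else frame


def simulate_scan(
    scene: Scene,
    n_frames: int,
    layout: "OpticalLayout",
    calib_truth: "CalibrationFit",
    illumination: Spectrum | None = None,
    smile: SmileModel | None = None,
    noise_sd: float = 2.0,
    rng_seed: int = 0,
    illumination_drift: float = 0.0,
    **render_kwargs,
):
    """Yield ``n_frames`` frames of the scene as the platform advances.

    Per-frame illumination amplitude drifts by a random-walk fraction
    ``illumination_drift`` to emulate changing natural light.
    """
    rng = np.random.default_rng(rng_seed)
    illum = illumination if illumination is not None else daylight_illumination()
    amp = 1.0
    for _ in range(n_frames):
        if illumination_drift > 0:
            amp = float(np.clip(amp * (1.0 + illumination_drift * rng.normal()),
                                0.3, 1.5))
        frame_illum = Spectrum(illum.wavelengths_nm, amp * illum.intensities)
        yield render_frame(scene, frame_illum, layout, calib_truth, smile=smile,
                           noise_sd=noise_sd, rng_seed=rng, **render_kwargs)


def make_leaf_dataset(
    n: int,
    seed: int = 0,
    class_b_fraction: float = 0.2425,
    n_bins: int = 50,
    range_nm: tuple[float, float] = (450.0, 950.0),
    amplitude_jitter: float = 0.15,
    angle_jitter: float = 0.5,
):
    """Population of binned leaf feature vectors for classifier studies.

    Returns ``(X, y, green_peak)``: ``X`` the (n, n_bins) binned
    reflectances, ``y`` the class labels (0 = A/lettuce-like,
    1 = B/arugula-like), and ``green_peak`` the raw visible-range maximum
    of each spectrum (the single scalar a threshold classifier would use).
    The default class-B fraction matches a roughly 3:1 class imbalance.
    """
    rng = np.random.default_rng(seed)
    grid = DEFAULT_GRID_NM
    edges = np.linspace(range_nm[0], range_nm[1], n_bins + 1)
    bin_idx = np.digitize(grid, edges) - 1
    in_range = (bin_idx >= 0) & (bin_idx < n_bins)
    counts = np.bincount(bin_idx[in_range], minlength=n_bins)
    vis = (grid >= 400.0) & (grid <= 700.0)

    n_b = int(round(class_b_fraction * n))
    y = np.zeros(n, dtype=int)
    y[n - n_b:] = 1
    X = np.empty((n, n_bins))
    green_peak = np.empty(n)
    for i in range(n):
        s = make_leaf_spectrum("B" if y[i] else "A", rng,
                               amplitude_jitter=amplitude_jitter,
                               angle_jitter=angle_jitter)
        v = s.intensities
        X[i] = np.bincount(bin_idx[in_range], weights=v[in_range],
                           minlength=n_bins) / counts
        green_peak[i] = v[vis].max()
    return X, y, green_peak


def leaf_panel_scene(
    white_frac: float = 0.06,
    leaf_a_frac: float = 0.38,
    gap_frac: float = 0.12,
    leaf_b_frac: float = 0.38,
    **leaf_params,
) -> Scene:
    """Bench scene: white reference panel, class-A leaves, bare ground gap,
    class-B leaves, trailing ground."""
    rest = 1.0 - (white_frac + leaf_a_frac + gap_frac + leaf_b_frac)
    if rest < 0:
        raise ValueError("fractions exceed 1")
    return Scene([
        Strip(white_frac, "white_panel"),
        Strip(leaf_a_frac, "leaf_class_A", dict(leaf_params)),
        Strip(gap_frac, "black_ground"),
        Strip(leaf_b_frac, "leaf_class_B", dict(leaf_params)),
        Strip(rest, "black_ground"),
    ])


def line_pattern_scene(
    periods_cm: Sequence[float],
    rows_per_cm: float,
    n_rows: int,
    lines_per_group: int = 4,
) -> tuple[Scene, list[tuple[int, int]]]:
    """Resolution test chart: groups of bright/dark bars of decreasing period.

    ``periods_cm`` is the full bar-pair period of each group. Returns the
    scene and the [start, stop) row range of each group. Groups are
    separated by dark spacers; leftover extent is dark ground.
    """
    strips: list[Strip] = []
    bounds: list[tuple[int, int]] = []
    row = 0
    spacer_rows = max(int(round(0.4 * rows_per_cm)), 8)
    for period in periods_cm:
        group_rows = int(round(lines_per_group * period * rows_per_cm))
        if row + group_rows + spacer_rows > n_rows:
            raise ValueError("pattern does not fit the spatial axis")
        strips.append(Strip(spacer_rows / n_rows, "black_ground"))
        row += spacer_rows
        strips.append(Strip(group_rows / n_rows, "line_pattern",
                            {"period_cm": float(period),
                             "rows_per_cm": float(rows_per_cm)}))
        bounds.append((row, row + group_rows))
        row += group_rows
    strips.append(Strip((n_rows - row) / n_rows, "black_ground"))
    # normalize any rounding drift in the extents
    total = sum(s.extent for s in strips)
    for s in strips:
        s.extent /= total
    return Scene(strips), bounds
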