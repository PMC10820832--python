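"""Reflectance extraction and spectral feature binning.

Reflectance is computed per spatial position by dividing each row's
spectrum, pixel by pixel, by the mean spectrum of a white reference panel
(assumed reflectance 1) imaged in the same frame. Because the panel sees
the same illumination and instrument response, both cancel in the ratio.
Spectra are then reduced to 50 features, each the mean reflectance over a
~10 nm wavelength bin, and positions whose mean reflectance falls below a
threshold are flagged as bare ground.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibrate import CalibrationFit

__all__ = [
    "ReflectanceLine",
    "FeatureVector",
    "compute_reflectance",
    "bin_features",
    "ground_filter",
    "feature_names",
]

SATURATION_LEVEL = 255.0


@dataclass
class ReflectanceLine:
    """Per-position reflectance spectra of one frame on the calibrated grid."""

    positions: np.ndarray           # spatial row indices, (n_rows,)
    wavelengths_nm: np.ndarray      # per retained spectral column, ascending
    reflectance: np.ndarray         # (n_rows, n_cols), >= 0 where unmasked
    mask: np.ndarray                # True where the reference was usable
    white_reference_rows: tuple[int, int]


@dataclass(frozen=True)
class FeatureVector:
    """50 binned reflectances for one spatial position."""

    features: np.ndarray
    bin_edges_nm: np.ndarray
    valid: bool = True
    reason: str = ""
    position: int = -1

    def __post_init__(self) -> None:
        if self.features.size != self.bin_edges_nm.size - 1:
            raise ValueError("need exactly one more bin edge than features")
        if np.any(np.diff(self.bin_edges_nm) <= 0):
            raise ValueError("bin edges must be strictly increasing")


def feature_names(bin_edges_nm: np.ndarray) -> list[str]:
    """CSV column names of the binned features, e.g. ``f450_460``."""
    e = np.asarray(bin_edges_nm)
    return [f"f{int(round(e[i]))}_{int(round(e[i + 1]))}" for i in range(e.size - 1)]


def compute_reflectance(
    frame: np.ndarray,
    fit: CalibrationFit,
    white_rows: tuple[int, int],
    floor: float = 5.0,
    sample_rows: np.ndarray | None = None,
) -> ReflectanceLine:
    """Reflectance of each spatial position against the white panel rows.

    ``frame`` must already be smile-remapped. Spectral pixels where the
    white reference does not rise above ``floor`` counts are masked. The
    reference region must be lit (mean above ``floor`` at >= 90% of the
    retained spectral pixels) and not saturated (< 60% of its pixels at
    full scale).
    """
    frame = np.asarray(frame, dtype=float)
    n_rows, n_cols = frame.shape
    r0, r1 = white_rows
    if not (0 <= r0 < r1 <= n_rows):
        raise ValueError("white reference rows outside the frame")

    # retain the columns the calibration maps to wavelengths
    cols = np.arange(n_cols, dtype=float)
    lam, col_valid = fit.pixel_to_wavelength(cols, strict=False)
    keep = np.flatnonzero(col_valid)
    if keep.size == 0:
        raise ValueError("calibration covers no sensor column")
    lam = lam[keep]
    order = np.argsort(lam)
    keep, lam = keep[order], lam[order]

    white_block = frame[r0:r1][:, keep]
    reference = white_block.mean(axis=0)
    if np.mean(white_block >= SATURATION_LEVEL) >= 0.6:
        raise ValueError("white reference region is saturated")
    usable = reference > floor
    if usable.mean() < 0.9:
        raise ValueError(
            "white reference too dark: above the floor at "
            f"{usable.mean():.0%} of spectral pixels (need >= 90%)")

    if sample_rows is None:
        sample_rows = np.concatenate(
            [np.arange(0, r0), np.arange(r1, n_rows)]).astype(int)
    else:
        sample_rows = np.asarray(sample_rows, dtype=int)
        if np.any((sample_rows >= r0) & (sample_rows < r1)):
            raise ValueError("sample rows must be disjoint from the white rows")

    refl = np.zeros((sample_rows.size, keep.size))
    refl[:, usable] = frame[sample_rows][:, keep[usable]] / reference[usable]
    return ReflectanceLine(
        positions=sample_rows,
        wavelengths_nm=lam,
        reflectance=refl,
        mask=np.broadcast_to(usable, refl.shape).copy(),
        white_reference_rows=(r0, r1),
    )


def bin_features(
    line: ReflectanceLine,
    n_bins: int = 50,
    range_nm: tuple[float, float] = (450.0, 950.0),
) -> list[FeatureVector]:
    """Reduce each position's spectrum to ``n_bins`` mean reflectances.

    Bin k covers the half-open interval [edge_k, edge_{k+1}); masked
    spectral pixels are excluded from the means, and a position whose bins
    are not all populated is returned invalid.
    """
    if n_bins < 1:
        raise ValueError("need at least one bin")
    lo, hi = range_nm
    lam = line.wavelengths_nm
    if lo < lam.min() - 1e-9 or hi > lam.max() + 1e-9:
        raise ValueError("binning range outside the calibrated wavelength span")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.digitize(lam, edges) - 1
    in_range = (idx >= 0) & (idx < n_bins)

    out: list[FeatureVector] = []
    for i, row in enumerate(line.positions):
        use = in_range & line.mask[i]
        counts = np.bincount(idx[use], minlength=n_bins)
        sums = np.bincount(idx[use], weights=line.reflectance[i][use],
                           minlength=n_bins)
        if np.any(counts == 0):
            out.append(FeatureVector(np.zeros(n_bins), edges, valid=False,
                                     reason="empty_bin", position=int(row)))
            continue
        out.append(FeatureVector(sums / counts, edges, valid=True,
                                 position=int(row)))
    return out


def ground_filter(vec: FeatureVector, threshold: float = 0.10) -> FeatureVector:
    """Invalidate positions with low integrated diffuse reflectance.

    Bare soil / black ground reflects an order of magnitude less than the
    leaf NIR plateau, so a threshold on the mean binned reflectance
    separates them; flagged vectors carry the reason ``"ground"``.
    """
    if not np.all(np.isfinite(vec.features)):
        raise ValueError("features must be finite")
    if not vec.valid:
        return vec
    if float(vec.features.mean()) < threshold:
        return replace(vec, valid=False, reason="ground")
    return vec
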