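"""Analytic forward model of the prism spectrograph.

The instrument is a slit spectrograph: a wide-angle objective images a
ground line onto a 200 um x 20 mm slit, a collimator/re-imager telescope
(f = 75 mm / 25 mm, magnification 1/3) relays the slit through an F2
equilateral prism onto a monochrome sensor, so that one sensor axis is
spatial (along the slit) and the other is spectral (prism dispersion).

This module provides the closed-form pieces of that chain: the one-term
Sellmeier refractive index of the prism glass, the two-refraction prism
exit angle, and the thin-lens ground-footprint arithmetic (line width and
length on the soil, sampling per pixel, inter-frame advance of a moving
platform).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PrismSpec",
    "OpticalLayout",
    "GroundFootprint",
    "sellmeier_index",
    "prism_exit_angle",
    "ground_footprint",
]

# One-term Sellmeier constants for F2 flint glass, obtained by a
# least-squares fit of n^2 = A + B*l^2/(l^2 - C) to the published
# three-term Schott F2 dispersion over 300-1000 nm (max |dn| < 2e-3).
F2_SELLMEIER_A = 1.757253876001689
F2_SELLMEIER_B = 0.7905123941079709
F2_SELLMEIER_C_NM2 = 30079.24596167551


@dataclass(frozen=True)
class PrismSpec:
    """Dispersing prism: geometry plus one-term Sellmeier glass model.

    Angles are degrees at the interface; ``sellmeier_C`` is in nm^2 so the
    index can be evaluated directly on wavelength grids in nm.
    """

    apex_angle_deg: float = 60.0
    incidence_angle_deg: float = 45.0
    sellmeier_A: float = F2_SELLMEIER_A
    sellmeier_B: float = F2_SELLMEIER_B
    sellmeier_C: float = F2_SELLMEIER_C_NM2

    def __post_init__(self) -> None:
        if not 0.0 < self.apex_angle_deg < 180.0:
            raise ValueError("apex angle must lie in (0, 180) degrees")


@dataclass(frozen=True)
class OpticalLayout:
    """Geometry of the collection and relay optics and the sensor.

    ``objective_focal_mm`` is the effective focal length of the collecting
    lens (26 mm including the sensor crop factor). Columns are the spectral
    axis, rows the spatial axis, matching the detector orientation where
    the horizontal sensor coordinate encodes wavelength.
    """

    objective_focal_mm: float = 26.0
    collimator_focal_mm: float = 75.0
    reimager_focal_mm: float = 25.0
    slit_width_um: float = 200.0
    slit_length_mm: float = 20.0
    working_distance_m: float = 1.2
    sensor_cols: int = 728
    sensor_rows: int = 544
    wavelength_range_nm: tuple[float, float] = (300.0, 1000.0)

    def __post_init__(self) -> None:
        for name in (
            "objective_focal_mm",
            "collimator_focal_mm",
            "reimager_focal_mm",
            "slit_width_um",
            "slit_length_mm",
            "working_distance_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sensor_cols < 1 or self.sensor_rows < 1:
            raise ValueError("sensor dimensions must be positive integers")
        lo, hi = self.wavelength_range_nm
        if not lo < hi:
            raise ValueError("wavelength range must be ascending")

    @property
    def magnification(self) -> float:
        """Telescope magnification M = f_reimager / f_collimator."""
        return self.reimager_focal_mm / self.collimator_focal_mm


@dataclass(frozen=True)
class GroundFootprint:
    """What one detector frame sees on the ground."""

    line_width_cm: float
    line_length_m: float
    cm_per_pixel: float
    nm_per_pixel: float
    interframe_shift_mm: float


def sellmeier_index(lambda_nm, prism: PrismSpec):
    """Refractive index n(lambda) from the one-term Sellmeier relation.

    n^2 = A + B*lambda^2 / (lambda^2 - C), lambda in nm, C in nm^2.

    Raises ``ValueError`` where lambda^2 <= C (index undefined).
    """
    lam = np.asarray(lambda_nm, dtype=float)
    lam2 = lam**2
    if np.any(lam2 <= prism.sellmeier_C):
        raise ValueError(
            "wavelength^2 must exceed the Sellmeier C constant "
            f"({prism.sellmeier_C} nm^2)"
        )
    n2 = prism.sellmeier_A + prism.sellmeier_B * lam2 / (lam2 - prism.sellmeier_C)
    if np.any(n2 <= 0):
        raise ValueError("non-physical Sellmeier constants: n^2 <= 0")
    n = np.sqrt(n2)
    return n if n.ndim else float(n)


def prism_exit_angle(lambda_nm, prism: PrismSpec):
    """Exit angle (degrees) of a ray traversing the prism at both faces.

    theta_out = theta0 + arcsin[ n * sin(alpha - arcsin(sin(theta0)/n)) ],
    the standard two-refraction result for a prism of apex angle alpha hit
    at incidence theta0. For normal dispersion (n decreasing with
    wavelength) theta_out decreases monotonically with wavelength, which
    is what spreads the spectrum across the sensor columns.

    Raises ``ValueError`` on total internal reflection at the exit face.
    """
    n = np.asarray(sellmeier_index(lambda_nm, prism), dtype=float)
    alpha = math.radians(prism.apex_angle_deg)
    theta0 = math.radians(prism.incidence_angle_deg)
    inner = np.arcsin(np.sin(theta0) / n)
    exit_arg = n * np.sin(alpha - inner)
    if np.any(np.abs(exit_arg) > 1.0):
        raise ValueError("total internal reflection at the prism exit face")
    out = np.degrees(theta0 + np.arcsin(exit_arg))
    return out if out.ndim else float(out)


def ground_footprint(
    layout: OpticalLayout,
    speed_kmh: float = 5.0,
    frame_rate_fps: float = 50.0,
) -> GroundFootprint:
    """Thin-lens projection of the slit onto the ground plus scan sampling.

    The slit of width ``w`` and length ``L`` at working distance ``d`` from
    an objective of focal length ``f`` selects a ground line of size
    ``w*(d-f)/f`` by ``L*(d-f)/f``. ``cm_per_pixel`` is the ground line
    length divided by the spatial (row) pixel count; ``nm_per_pixel`` is
    the nominal wavelength span divided by the spectral (column) pixel
    count. ``interframe_shift_mm`` is the platform advance between
    consecutive frames, speed / frame rate.
    """
    if speed_kmh <= 0 or frame_rate_fps <= 0:
        raise ValueError("speed and frame rate must be strictly positive")
    d_mm = layout.working_distance_m * 1000.0
    f_mm = layout.objective_focal_mm
    if d_mm <= f_mm:
        raise ValueError("working distance must exceed the objective focal length")
    projection = (d_mm - f_mm) / f_mm
    line_width_cm = layout.slit_width_um * 1e-4 * projection
    line_length_m = layout.slit_length_mm * 1e-3 * projection
    lo, hi = layout.wavelength_range_nm
    return GroundFootprint(
        line_width_cm=line_width_cm,
        line_length_m=line_length_m,
        cm_per_pixel=line_length_m * 100.0 / layout.sensor_rows,
        nm_per_pixel=(hi - lo) / layout.sensor_cols,
        interframe_shift_mm=speed_kmh * 1e6 / 3600.0 / frame_rate_fps,
    )
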