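"""Spatial and spectral resolution characterization.

Renders a bar-target chart (groups of bright/dark bars of shrinking
period) along the slit, measures the modulation contrast
C = (Imax-Imin)/(Imax+Imin) per group, interpolates the period at which
C crosses 0.5, checks spacing linearity, and measures the FWHM of a sharp
540 nm emission line as the spectral resolution.
"""

import numpy as np

from pushbroom import IntensityProfile, OpticalLayout, Scene, Strip, \
    analyze_line_pattern, default_calibration, ground_footprint, \
    spacing_linearity, spectral_resolution
from pushbroom.simulate import Spectrum, flat_illumination, \
    line_pattern_scene, make_lamp_spectrum, render_frame

layout = OpticalLayout()
truth = default_calibration(layout)
fp = ground_footprint(layout)
rows_per_cm = layout.sensor_rows / (fp.line_length_m * 100.0)

# bar-pair periods in cm on the ground; at 0.166 cm/px sampling the
# smallest group falls below the blur width and merges into one peak
periods = [3.0, 2.0, 1.0, 0.5]
scene, bounds = line_pattern_scene(periods, rows_per_cm, layout.sensor_rows)
frame = render_frame(scene, flat_illumination(), layout, truth,
                     noise_sd=1.0, spatial_lsf_fwhm_px=3.0, rng_seed=0)
profile = IntensityProfile(np.arange(layout.sensor_rows, dtype=float),
                           frame.mean(axis=1))

report = analyze_line_pattern(profile, bounds, periods)
print("bar-target contrast per group:")
for g in report.groups:
    state = "resolved" if g.resolved else "UNRESOLVED (single merged peak)"
    print(f"  period {g.pattern_period_cm:5.2f} cm  "
          f"C = {g.contrast:5.3f}  {state}")
print(f"spatial resolution at C = 0.5: "
      f"{report.resolution_at_half_contrast_cm:.3f} cm")

slope, intercept, max_resid = spacing_linearity(profile, bounds, periods)
print(f"\npeak-spacing linearity: {slope:.1f} px/cm, "
      f"max residual {max_resid:.2f} px "
      "(sub-pixel residuals mean no measurable geometric distortion)")

sharp = render_frame(Scene([Strip(1.0, "white_panel")]),
                     make_lamp_spectrum([540.0], 0.5, 1.0), layout, truth,
                     noise_sd=0.0)
line = sharp[200:344].mean(axis=0)
cols = np.arange(line.size, dtype=float)
lam, valid = truth.pixel_to_wavelength(cols, strict=False)
result = spectral_resolution(Spectrum(lam[valid], line[valid]), 540.0)
print(f"\nspectral resolution (FWHM of the 540 nm line): "
      f"{result.fwhm_nm:.1f} nm (< 20 nm)")
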