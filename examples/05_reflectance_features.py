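"""Per-position reflectance spectra and 50-bin feature vectors.

Renders a bench frame, remaps the smile, divides every spatial row by the
white-panel reference (canceling illumination and instrument response),
reduces each spectrum to 50 mean reflectances over 10 nm bins, and flags
bare-ground rows by their low integrated reflectance.
"""

import numpy as np

from pushbroom import OpticalLayout, SmileModel, bin_features, \
    compute_reflectance, default_calibration, ground_filter, remap_frame
from pushbroom.simulate import daylight_illumination, leaf_panel_scene, \
    render_frame

layout = OpticalLayout()
smile = SmileModel.quadratic(4.0)
truth = default_calibration(layout, smile=smile)
scene = leaf_panel_scene()

frame = render_frame(scene, daylight_illumination(), layout, truth,
                     smile=smile, noise_sd=2.0, rng_seed=0)
remapped = remap_frame(frame, truth)
line = compute_reflectance(remapped, truth, white_rows=(0, 33))
vectors = [ground_filter(v) for v in bin_features(line)]

print(f"{len(vectors)} spatial positions, features over "
      f"{vectors[0].bin_edges_nm[0]:.0f}-{vectors[0].bin_edges_nm[-1]:.0f} nm "
      f"in {vectors[0].features.size} bins of "
      f"{np.diff(vectors[0].bin_edges_nm)[0]:.0f} nm")
n_ground = sum(not v.valid for v in vectors)
print(f"{n_ground} positions flagged as ground "
      "(mean reflectance below 0.10)")

for (a, b), strip in zip(scene.row_ranges(layout.sensor_rows), scene.strips):
    rows = [v for v in vectors if a + 3 <= v.position < b - 3]
    if not rows:
        continue
    feats = np.stack([v.features for v in rows])
    green = feats[:, 10:15].mean()   # 550-600 nm bins
    nir = feats[:, 30:50].mean()     # 750-950 nm bins
    print(f"  {strip.material:13s} rows {a:3d}-{b:3d}: "
          f"green {green:5.3f}, NIR {nir:5.3f}, "
          f"valid {sum(v.valid for v in rows)}/{len(rows)}")
print("leaves show the NIR plateau well above the green peak; "
      "ground rows sit near zero everywhere")
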