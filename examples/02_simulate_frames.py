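"""Render synthetic detector frames of a leaf bench scene.

The scene along the slit is [white panel | lettuce-like leaves | bare
ground | arugula-like leaves | ground]. Frames include prism dispersion,
a 4 px spectral smile, instrument line spread, noise and Mono8
quantization, and are written both as PNGs and as one ENVI BIL cube.
"""

from pathlib import Path

import numpy as np

from pushbroom import OpticalLayout, SmileModel, default_calibration, \
    simulate_scan
from pushbroom.io import write_envi_cube, write_frame
from pushbroom.simulate import leaf_panel_scene

out = Path("scratch/example_scan")
out.mkdir(parents=True, exist_ok=True)

layout = OpticalLayout()
smile = SmileModel.quadratic(4.0)
truth = default_calibration(layout, smile=smile)
scene = leaf_panel_scene()

frames = list(simulate_scan(scene, 5, layout, truth, smile=smile,
                            noise_sd=2.0, rng_seed=0))
for i, frame in enumerate(frames):
    write_frame(out / f"frame_{i:04d}.png", frame)
write_envi_cube(out / "scan.hdr", np.stack(frames))

frame = frames[0]
print(f"wrote {len(frames)} frames ({frame.shape[0]} spatial rows x "
      f"{frame.shape[1]} spectral columns, {frame.dtype}) to {out}/")
for (a, b), strip in zip(scene.row_ranges(layout.sensor_rows), scene.strips):
    band = frame[a:b].mean()
    print(f"  rows {a:3d}-{b:3d}  {strip.material:13s} "
          f"mean counts {band:6.1f}")
print("bright rows are the white panel; leaf strips are dimmer with the "
      "NIR plateau visible at the right of the spectral axis")
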