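# Methods

## Instrument model

The modelled instrument is a slit spectrograph: an f = 26 mm wide-angle
objective (effective focal length including the sensor crop factor)
images the ground onto a 200 µm × 20 mm slit; an f = 75 mm collimator and
f = 25 mm re-imager (telescope magnification M = 1/3) relay the slit
through an equilateral F2 prism onto a 728 × 544 px monochrome sensor.
Rows are spatial positions along the slit, columns the spectral axis —
this is the default and can be swapped in `OpticalLayout` for hardware
with the opposite orientation.

Ground-footprint arithmetic uses the thin-lens projection (d−f)/f, which
at the "about 1 cm × 1 m" level is indistinguishable from the exact
imaging equation. At the nominal working distance d = 1.2 m the slit
maps to a 0.903 cm × 0.903 m ground line, i.e. 0.166 cm per spatial
pixel, and the 300–1000 nm band over 728 columns gives a nominal
0.96 nm per spectral pixel. The per-frame platform advance is
speed/frame-rate with no shortcuts: note that 5 km/h at 50 fps advances
27.8 mm per frame; a sub-3 mm advance requires either a ~14 cm/s crawl
at 50 fps or the camera's full 495 fps at 5 km/h. The footprint function
reports whatever the caller's speed and rate imply.

### Dispersion

The prism glass follows a one-term Sellmeier form
n²(λ) = A + Bλ²/(λ²−C) with λ in nm and C in nm². The bundled defaults
(A = 1.757254, B = 0.790512, C = 30079.2 nm²) were obtained by
least-squares fit to the published three-term F2 dispersion over
300–1000 nm; the one-term approximation tracks the full form to better
than 2×10⁻³ in n across the band (3.5×10⁻⁴ at 540 nm). All three
constants are overridable through `PrismSpec`.

The exit angle uses the standard two-refraction prism formula
θout = θ0 + arcsin[n·sin(α − arcsin(sin θ0 / n))] (apex α, incidence θ0,
angles in degrees at the interface, radians internally). It reproduces
the n = 1 limit (θout = α) and the minimum-deviation symmetry
(sin θ0 = n sin(α/2) ⇒ θout = 2θ0), and is verified against an explicit
two-interface Snell trace to < 10⁻⁹ degrees. Total internal reflection at
the exit face raises an error rather than returning a complex angle; for
F2 at α = 60° that bounds usable incidence angles to roughly θ0 ≳ 40°.

### Wavelength-to-pixel map

Linearizing the exit angle in n and substituting the Sellmeier form
gives pixel(λ) = A′ + B′·√(λ²/(λ²−C)) + D. A′ and D are both additive
constants and not separately identifiable, so D is fixed at zero and the
three remaining parameters are fitted — the fitted curve is identical.
The map is strictly monotone for B′ ≠ 0, C ≠ 0 and has the closed-form
inverse λ = √(C s²/(s²−1)) with s = (pixel−A′)/B′, used directly (with
domain checks) instead of numerical root finding; round-trips hold to
10⁻⁶ nm. C = 0 makes the map flat and is rejected as degenerate.

Fitting is Levenberg–Marquardt least squares initialized at
A′ = mean(pixel), B′ = −range(pixel), C = (250 nm)², with up to three
seeded, jittered restarts; fits require ≥ 4 peaks spanning ≥ 200 nm and
are rejected if the result is non-monotone. Sub-pixel peak columns come
from three-point parabolic interpolation around `scipy.signal`
local maxima of a row-band mean profile. Column coordinates are 0-based
with pixel centers at integers, stated in every file written.

### Spectral smile

The smile — the wavelength axis shifting horizontally with spatial row —
is modelled as shift(u) = a₁u + a₂u² in the normalized row coordinate
u ∈ [−1, 1], zero at the center row. The simulator injects a pure
quadratic by default; estimation fits the per-row sub-pixel peak columns
of monochromatic frames with a quadratic and averages coefficients over
frames (≥ 10 usable rows required). Correction shifts each row by the
negated profile with linear interpolation (bicubic adds nothing at the
0.01 px residual level reached on synthetic frames, where a 4 px smile is
straightened ~90×). Remapped frames are float64 so correction adds no
second quantization.

## Synthetic data

The simulator emulates the bench data this pipeline consumes: a scene is
an ordered partition of the slit line into material strips (white
reference panel of reflectance 1.0, black ground at 0.03, leaf classes,
bar targets, or explicit custom spectra). Per row, radiance =
reflectance × illumination is sampled at the wavelength the truth
calibration assigns to each column (shifted by the smile), convolved with
a Gaussian line spread (default 6 px spectral, 3 px spatial), scaled by
an exposure of 200 counts, noised (default σ = 2 counts), clipped and
quantized to Mono8. A float dialect skips quantization for unit tests.
All randomness flows through one explicit seeded generator.

Leaf reflectance is parametric rather than radiative-transfer based: a
baseline with a weak blue bump, a green Gaussian peak near 550 nm, a
chlorophyll absorption dip at 670 nm, and a logistic red edge rising to
the NIR plateau. The two classes differ in the green-peak amplitude
distribution — N(0.30, 0.05) vs N(0.22, 0.05), deliberately overlapping —
and more subtly in red-edge inflection (711 vs 723 nm), peak width and
NIR level. Two multiplicative factors (a 15 % Gaussian brightness jitter
and a random foreshortening cosine up to 60°·angle_jitter) emulate
leaf-to-leaf albedo and viewing-angle variation; they rescale the whole
spectrum, which is exactly why absolute amplitude is a poor class cue
while band ratios survive. These defaults were chosen so the simulated
population reproduces the qualitative difficulty of the real task: the
best single green-peak threshold stays around 0.80 accuracy (amplitude
distributions overlap with coefficient ≈ 0.56) while the full spectral
shape remains separable. What passing tests show is therefore that the
pipeline recovers and exploits spectral shape under realistic amplitude
confounds — not that real lettuce/arugula spectra are this clean. Real
data add specular glints, soil-spectrum mixing at leaf edges, shadowing
and illumination colour changes that the generator does not model
(illumination varies only by a smooth per-frame amplitude drift).

## Reflectance and features

Reflectance is the per-pixel ratio of each spatial row's spectrum to the
mean spectrum of the white-panel rows of the same frame, so illumination
and spectral responsivity cancel identically in simulation; the panel is
re-estimated every frame, matching a reference panel traveling in the
field of view. Spectral pixels where the reference does not exceed a
floor (default 5 counts) are masked; a reference that is dark at > 10 %
of pixels or saturated over ≥ 60 % of its area is rejected.

Features are means over 50 half-open 10 nm bins spanning 450–950 nm — a
range chosen to cover the green peak through the NIR plateau while
staying where the simulated dispersion provides ≥ 1 column per bin (the
red end of the band runs at ~8–10 nm/px); both range and count are
configurable. The mean (vs median) matches the noise-averaging intent of
binning. A vector with an empty bin is invalid rather than silently
interpolated. The ground filter invalidates positions whose mean binned
reflectance falls below 0.10 — black ground and the leaf NIR plateau
differ by an order of magnitude, so the threshold is uncritical; it is
exposed in `PipelineConfig`.

## Classifier

The model is scikit-learn's MLPClassifier configuration distilled to its
arithmetic: 50 inputs → 25 relu nodes → 1 logistic output, adam with
binary cross-entropy, max 500 iterations. Loss function, batch size
(200), learning rate (10⁻³) and the absence of feature standardization
are exposed defaults — reflectance features already live in ~[0, 1].
Training is delegated to scikit-learn; the fitted weights are extracted
into a JSON-serializable model whose forward pass is implemented here
and cross-checked against a scalar-loop oracle, so stored models run
without the training stack and diff cleanly. The decision threshold is
0.5; class 1 is the arugula-like class.

The 0.7/0.3 split takes the ceiling on the test side,
test = ⌈0.3·total⌉ — the convention that maps 296,862 total spectra to
207,803 train / 89,059 test. Splits are non-stratified random
permutations. Evaluation reports the 2×2 confusion matrix (rows = true),
per-class precision/recall/F and accuracy; metrics with an empty
denominator are NaN-flagged as undefined, never silently zero.

## Streaming

The real-time loop is stateless across frames: each frame independently
goes remap → reflectance → bin → ground filter → classify, producing one
record (positions, labels, logistic scores; ground positions carry no
score) written as a JSON line. Statelessness makes streaming output
bit-equal to batch classification and keeps memory bounded at one frame.
Unreadable frames are skipped with a logged warning. Latency is measured
and reported but never asserted — it is hardware-dependent.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 200 Monte-Carlo
replicates for the calibration study (8 peaks, 0.3 px noise, 4 held-out
wavelengths), single 544 × 728 frames for smile/reflectance studies,
20,000 spectra for the classifier study, and 100 frames for the
streaming equivalence check — sizes at which every quantity is stable to
well inside its test tolerance across seeds. Degenerate inputs fail
loudly throughout: flat frames, single-class training sets, saturated or
dark references, non-monotone fits, out-of-domain wavelengths.

## Known limitations

- The forward model is analytic; there is no ray-traced aberration,
  keystone distortion, stray light or detector fixed-pattern noise.
- Smile is at most quadratic in row; higher-order curvature would alias
  into the residual of the quadratic fit.
- Reflectance assumes the white panel is unsaturated and Lambertian;
  no BRDF or angle correction is attempted (angular variability is
  instead embraced as training diversity).
- The spatial-resolution machinery is exercised on synthetic bar targets;
  it characterizes the simulated line spread, not any physical optic.
- Leaf classes are a two-species parametric family; transferring the
  trained model to real spectra would require retraining on measured
  data.
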