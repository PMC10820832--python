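import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pushbroom import calibrate as cal
from pushbroom import reflectance as refl
from pushbroom import simulate as sim


def uniform_frame(layout, truth, reflectance=1.0, illum_amp=1.0,
                  noise_sd=0.0, dialect="float"):
    scene = sim.Scene([sim.Strip(1.0, "white_panel",
                                 {"reflectance": reflectance})])
    return sim.render_frame(scene, sim.flat_illumination(illum_amp), layout,
                            truth, noise_sd=noise_sd, dialect=dialect)


class TestComputeReflectance:
    def test_self_normalization_gives_unity(self, layout, truth_calibration):
        frame = uniform_frame(layout, truth_calibration)
        line = refl.compute_reflectance(frame, truth_calibration, (0, 30))
        assert np.allclose(line.reflectance[line.mask], 1.0, atol=1e-9)

    def test_illumination_scaling_cancels(self, layout, truth_calibration):
        scene = sim.leaf_panel_scene(amplitude_jitter=0.0, angle_jitter=0.0)
        frames = [
            sim.render_frame(scene, sim.flat_illumination(a), layout,
                             truth_calibration, noise_sd=0.0, rng_seed=5,
                             dialect="float")
            for a in (0.4, 0.8)
        ]
        lines = [refl.compute_reflectance(f, truth_calibration, (0, 33))
                 for f in frames]
        assert np.allclose(lines[0].reflectance, lines[1].reflectance,
                           atol=1e-9)

    def test_noise_free_recovery_within_quantization(self, layout,
                                                     truth_calibration):
        # known flat 0.5 reflectance against the white panel, Mono8 output
        scene = sim.Scene([
            sim.Strip(0.1, "white_panel"),
            sim.Strip(0.9, "white_panel", {"reflectance": 0.5}),
        ])
        frame = sim.render_frame(scene, sim.flat_illumination(1.0), layout,
                                 truth_calibration, noise_sd=0.0)
        line = refl.compute_reflectance(frame, truth_calibration, (0, 54))
        mid = line.reflectance[50][line.mask[50]]
        assert np.max(np.abs(mid - 0.5)) <= 1.0 / 128.0

    def test_saturated_reference_rejected(self, layout, truth_calibration):
        frame = uniform_frame(layout, truth_calibration, illum_amp=10.0,
                              dialect="mono8")
        with pytest.raises(ValueError, match="saturated"):
            refl.compute_reflectance(frame, truth_calibration, (0, 30))

    def test_dark_reference_rejected(self, layout, truth_calibration):
        frame = uniform_frame(layout, truth_calibration, illum_amp=1e-4)
        with pytest.raises(ValueError, match="too dark"):
            refl.compute_reflectance(frame, truth_calibration, (0, 30))

    def test_white_rows_disjoint_from_samples(self, layout,
                                              truth_calibration):
        frame = uniform_frame(layout, truth_calibration)
        line = refl.compute_reflectance(frame, truth_calibration, (0, 30))
        assert not np.any((line.positions >= 0) & (line.positions < 30))
        with pytest.raises(ValueError):
            refl.compute_reflectance(frame, truth_calibration, (0, 30),
                                     sample_rows=np.array([5, 40]))


class TestBinFeatures:
    def make_line(self, truth, values):
        lam = np.linspace(450.0, 950.0, 500)
        n_rows = values.shape[0]
        return refl.ReflectanceLine(
            positions=np.arange(n_rows),
            wavelengths_nm=lam,
            reflectance=values,
            mask=np.ones_like(values, dtype=bool),
            white_reference_rows=(0, 0),
        )

    def test_constant_reflectance_preserved(self, truth_calibration):
        line = self.make_line(truth_calibration, np.full((3, 500), 0.7))
        for vec in refl.bin_features(line):
            assert vec.valid
            assert np.allclose(vec.features, 0.7)

    def test_single_bin_equals_direct_mean(self, truth_calibration):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, size=(2, 500))
        line = self.make_line(truth_calibration, values)
        vecs = refl.bin_features(line, n_bins=1, range_nm=(450.0, 950.0))
        # oracle: brute-force mean over the range (one sample falls on the
        # closing edge and is excluded by the half-open convention)
        inside = line.wavelengths_nm < 950.0
        for vec, row in zip(vecs, values):
            assert vec.features[0] == pytest.approx(row[inside].mean(),
                                                    rel=1e-12)

    def test_default_bins_are_10nm(self, truth_calibration):
        line = self.make_line(truth_calibration, np.full((1, 500), 0.5))
        vec = refl.bin_features(line)[0]
        assert np.allclose(np.diff(vec.bin_edges_nm), 10.0)
        assert vec.features.size == 50

    def test_masked_pixels_excluded(self, truth_calibration):
        values = np.full((1, 500), 0.4)
        line = self.make_line(truth_calibration, values)
        # poison some pixels but keep them masked out
        line.reflectance[0, ::7] = 99.0
        line.mask[0, ::7] = False
        vec = refl.bin_features(line)[0]
        assert vec.valid
        assert np.allclose(vec.features, 0.4)

    def test_empty_bin_invalidates_vector(self, truth_calibration):
        values = np.full((1, 500), 0.4)
        line = self.make_line(truth_calibration, values)
        lam = line.wavelengths_nm
        line.mask[0, (lam >= 700) & (lam < 710)] = False
        vec = refl.bin_features(line)[0]
        assert not vec.valid and vec.reason == "empty_bin"

    def test_range_outside_calibration_rejected(self, truth_calibration):
        line = self.make_line(truth_calibration, np.full((1, 500), 0.5))
        with pytest.raises(ValueError):
            refl.bin_features(line, range_nm=(300.0, 950.0))


class TestGroundFilter:
    def make_vec(self, value):
        edges = np.linspace(450.0, 950.0, 51)
        return refl.FeatureVector(np.full(50, value), edges)

    def test_dark_vector_invalidated(self):
        out = refl.ground_filter(self.make_vec(0.0))
        assert not out.valid and out.reason == "ground"

    def test_white_panel_vector_stays_valid(self):
        assert refl.ground_filter(self.make_vec(1.0)).valid

    @settings(derandomize=True, max_examples=40)
    @given(value=st.floats(0.0, 1.0), t_lo=st.floats(0.0, 1.0),
           t_hi=st.floats(0.0, 1.0))
    def test_monotone_in_threshold(self, value, t_lo, t_hi):
        t_lo, t_hi = min(t_lo, t_hi), max(t_lo, t_hi)
        vec = self.make_vec(value)
        if refl.ground_filter(vec, t_hi).valid:
            assert refl.ground_filter(vec, t_lo).valid

    def test_nonfinite_features_rejected(self):
        vec = self.make_vec(0.5)
        vec.features[3] = np.nan
        with pytest.raises(ValueError):
            refl.ground_filter(vec)


class TestEndToEnd:
    def test_recovers_truth_bins_within_rms(self, layout, truth_with_smile,
                                            smile_4px):
        # render a fixed leaf spectrum, remap, normalize, bin; compare with
        # the 50-bin average of the generating reflectance
        leaf = sim.make_leaf_spectrum("A", rng_seed=7, amplitude_jitter=0.0,
                                      angle_jitter=0.0)
        scene = sim.Scene([
            sim.Strip(0.06, "white_panel"),
            sim.Strip(0.74, "custom", {"spectrum": leaf}),
            sim.Strip(0.20, "black_ground"),
        ])
        frame = sim.render_frame(scene, sim.daylight_illumination(), layout,
                                 truth_with_smile, smile=smile_4px,
                                 noise_sd=2.0, rng_seed=1)
        remapped = cal.remap_frame(frame, truth_with_smile)
        line = refl.compute_reflectance(remapped, truth_with_smile, (0, 33))
        vecs = refl.bin_features(line)

        edges = np.linspace(450.0, 950.0, 51)
        grid = leaf.wavelengths_nm
        idx = np.digitize(grid, edges) - 1
        ok = (idx >= 0) & (idx < 50)
        truth_bins = (np.bincount(idx[ok], weights=leaf.intensities[ok],
                                  minlength=50)
                      / np.bincount(idx[ok], minlength=50))

        feats = np.stack([v.features for v in vecs
                          if v.valid and 40 <= v.position < 380])
        rms = np.sqrt(np.mean((feats - truth_bins) ** 2))
        assert rms <= 0.02

    def test_black_ground_rows_flagged(self, layout, truth_calibration):
        scene = sim.Scene([
            sim.Strip(0.06, "white_panel"),
            sim.Strip(0.94, "black_ground"),
        ])
        flagged = total = 0
        for seed in range(2):  # ~1000 rendered ground rows
            frame = sim.render_frame(scene, sim.daylight_illumination(),
                                     layout, truth_calibration, noise_sd=2.0,
                                     rng_seed=seed)
            line = refl.compute_reflectance(frame, truth_calibration, (0, 33))
            for v in refl.bin_features(line):
                total += 1
                if not refl.ground_filter(v).valid:
                    flagged += 1
        assert total >= 1000
        assert flagged / total >= 0.99
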