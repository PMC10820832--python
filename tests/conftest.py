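import numpy as np
import pytest

from pushbroom import calibrate as cal
from pushbroom import classify as cls
from pushbroom import simulate as sim
from pushbroom.optics import OpticalLayout


@pytest.fixture(scope="session")
def layout():
    return OpticalLayout()


@pytest.fixture(scope="session")
def truth_calibration(layout):
    """Ground-truth dispersion mapping without smile."""
    return cal.default_calibration(layout)


@pytest.fixture(scope="session")
def smile_4px():
    return sim.SmileModel.quadratic(4.0)


@pytest.fixture(scope="session")
def truth_with_smile(layout, smile_4px):
    return cal.default_calibration(layout, smile=smile_4px)


@pytest.fixture(scope="session")
def mono540_frame(layout, truth_with_smile, smile_4px):
    """Noise-free monochromatic 540 nm frame with a 4 px quadratic smile."""
    lamp = sim.make_lamp_spectrum([540.0], 2.0, 1.0)
    scene = sim.Scene([sim.Strip(1.0, "white_panel")])
    return sim.render_frame(scene, lamp, layout, truth_with_smile,
                            smile=smile_4px, noise_sd=0.0, lsf_fwhm_px=3.0)


@pytest.fixture(scope="session")
def leaf_dataset_small():
    """Binned two-class leaf population, small enough for unit tests."""
    X, y, green_peak = sim.make_leaf_dataset(4000, seed=0)
    return cls.LabeledDataset(X, y, provenance="simulated n=4000 seed=0"), green_peak


@pytest.fixture(scope="session")
def trained_model(leaf_dataset_small):
    data, _ = leaf_dataset_small
    tr, _ = cls.split_indices(len(data), 0.7, seed=0)
    return cls.train(data.subset(tr), seed=0)
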