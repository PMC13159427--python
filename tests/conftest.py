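"""Shared fixtures: a small noise-free demo run and its SSN products."""

import numpy as np
import pytest

from ssnmsi import annotation, msi_io, ssn_core
from ssnmsi import synthetic_data as syn

DEMO_WINDOW = 808.6


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Noise-free three-species demo window: (dataset, truth, records)."""
    out = tmp_path_factory.mktemp("demo") / "demo.mzML"
    phantom, species, acq = syn.demo_window_scenario(seed=1)
    path, truth = syn.simulate_dataset(
        phantom, species, acq, syn.NoiseModel.none(), seed=1, out_path=out
    )
    records = msi_io.read_mzml(path)
    dataset = msi_io.assign_pixels(records, truth.grid, truth.line_breaks)
    return dataset, truth, records


@pytest.fixture(scope="session")
def demo_images(demo_run):
    """Detected product ions of the demo window and their images."""
    dataset, _, _ = demo_run
    filt = dataset.find_ms2_filter(DEMO_WINDOW)
    ions = msi_io.detect_product_ions(dataset, filt)
    images = [msi_io.extract_ion_image(dataset, filt, m, 0.3) for m in ions]
    return ions, images


@pytest.fixture(scope="session")
def demo_library():
    return annotation.load_library(annotation.demo_library_path())


def image_from_array(values, mask=None, target_mz=100.0):
    """Convenience: wrap a 2-D array as an IonImage with a full valid mask."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    return msi_io.IonImage(
        values=values, valid_mask=np.asarray(mask, dtype=bool),
        target_mz=target_mz, tolerance=0.3,
    )


@pytest.fixture
def make_image():
    return image_from_array
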