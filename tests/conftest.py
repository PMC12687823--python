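import numpy as np
import pytest

from lensrecon.io import Calibration, pixels_to_mm
from lensrecon.phantom import AcquisitionProtocol, OpticalMedia, forward_simulate, make_phantom


@pytest.fixture(scope="session")
def young_adult():
    return make_phantom("young_adult")


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol(noise_sd_px=0.0, rng_seed=7)


@pytest.fixture(scope="session")
def calibration():
    return Calibration()


@pytest.fixture(scope="session")
def on_axis_model(young_adult, protocol, calibration):
    """Corrected on-axis model of the standard phantom (shared: expensive)."""
    from lensrecon.raytrace import correct_model
    from lensrecon.zernike import assemble_model

    meridians = forward_simulate(young_adult, protocol, "on_axis")
    raw = assemble_model([pixels_to_mm(m, calibration) for m in meridians], "on_axis")
    return correct_model(raw, young_adult.media)


@pytest.fixture(scope="session")
def full_pipeline_result(young_adult, protocol):
    """Noise-free 8-orientation reconstruction of the standard phantom."""
    from lensrecon.pipeline import LensReconstruction

    return LensReconstruction.from_phantom(young_adult, protocol).fit()


@pytest.fixture(scope="session")
def training_basis():
    from lensrecon.eigenlens import build_basis, synthetic_training_population

    grids, meta = synthetic_training_population(40, rng=0)
    return build_basis(grids, K=6, meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
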