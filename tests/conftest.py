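import numpy as np
import pytest

from psrdose.model import Jaw, build_toy_beam_model
from psrdose.transport import DoseGrid
from psrdose import synthetic as syn


@pytest.fixture(scope="session")
def small_model():
    """4 rings x 3 energy bins x 3 classes = 36 sub-sources."""
    return build_toy_beam_model(4, 3)


@pytest.fixture(scope="session")
def test_phantom():
    """15 cm water cube at 100 cm SSD, 5 mm voxels."""
    return syn.make_default_phantom("test")


@pytest.fixture(scope="session")
def iso_phantom():
    """15 cm water cube centered on the isocenter, for rotating beams."""
    return DoseGrid.empty((-7.5, -7.5, 92.5), (0.5, 0.5, 0.5), (30, 30, 30))


@pytest.fixture(scope="session")
def study():
    """The default synthetic commissioning study, noise-free."""
    return syn.run_study(syn.SyntheticStudySpec(noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_measurements(study):
    """Measurements from the same study matrix with 0.2% dmax-dose noise."""
    return syn.make_synthetic_measurements(study.A, study.x_true,
                                           noise_sigma=0.2, rng_seed=77)
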