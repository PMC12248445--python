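import numpy as np
import pytest

import lipidmsi as lm
from lipidmsi import preprocess as pp
from lipidmsi import profiles_stats as ps
from lipidmsi import synthetic_data as sd


@pytest.fixture(scope="session")
def panel():
    return lm.default_panel()


@pytest.fixture(scope="session")
def banded_phantom():
    return lm.make_phantom(64, 64, "banded")


@pytest.fixture(scope="session")
def control_section(banded_phantom):
    """One default-noise control section (seeded) with its ground truth."""
    return lm.simulate_section(
        banded_phantom, lm.default_group_profiles("control"),
        sd.AcquisitionParams(), seed=7, group="control")


@pytest.fixture(scope="session")
def control_matrix(control_section):
    cube, _ = control_section
    return pp.run_preprocessing(cube)


@pytest.fixture(scope="session")
def control_annotations(control_matrix, panel):
    return ps.annotate_features(control_matrix, panel)


@pytest.fixture(scope="session")
def zero_noise_section(banded_phantom):
    return lm.simulate_section(
        banded_phantom, lm.default_group_profiles("control"),
        sd.AcquisitionParams.zero_noise(), seed=0, group="control")


@pytest.fixture(scope="session")
def tissue_labels_for(control_matrix, banded_phantom):
    grid = banded_phantom.label_grid
    return np.array([grid[r, c] for r, c in control_matrix.pixel_index])
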