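import numpy as np
import pytest

from efeg.experiment_data import (
    FIELD_KINDS,
    build_source_space,
    calibrate_amplitude,
    dipole_gain_matrix,
    make_montage,
    patch_gain,
)
from efeg.forward_spherical import default_head_model
from efeg.geometry import synthetic_cortex


@pytest.fixture(scope="session")
def head_model():
    return default_head_model()


@pytest.fixture(scope="session")
def cortex3():
    """Reduced cortex (subdivision 3: 642 vertices, 162 patch centers per
    hemisphere) used by most pipeline tests."""
    return synthetic_cortex(subdivision=3)


@pytest.fixture(scope="session")
def patches3(cortex3):
    return build_source_space(cortex3)


@pytest.fixture(scope="session")
def montage_v():
    return make_montage(128, 0.0, ("V",))


@pytest.fixture(scope="session")
def montage_f():
    return make_montage(128, 0.0, FIELD_KINDS)


@pytest.fixture(scope="session")
def gain_dip_v3(head_model, cortex3, montage_v):
    return dipole_gain_matrix(head_model, cortex3, montage_v)


@pytest.fixture(scope="session")
def gain_v3(head_model, cortex3, patches3, montage_v, gain_dip_v3):
    return patch_gain(head_model, cortex3, patches3, montage_v, dipole_gain=gain_dip_v3)


@pytest.fixture(scope="session")
def gain_f3(head_model, cortex3, patches3, montage_f):
    return patch_gain(head_model, cortex3, patches3, montage_f)


@pytest.fixture(scope="session")
def amplitude3(gain_v3):
    return calibrate_amplitude(gain_v3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
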