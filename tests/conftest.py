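import numpy as np
import pytest

from edemaquant import (
    AcquisitionParams,
    SyntheticStudyConfig,
    default_groups,
    generate_phantom,
)


@pytest.fixture(scope="session")
def tes():
    """Default 12-echo train, 6.5 ms spacing."""
    return np.asarray(AcquisitionParams().echo_times)


@pytest.fixture(scope="session")
def small_params():
    """Down-scaled acquisition grid for fast image-domain tests."""
    return AcquisitionParams(matrix_rows=48, matrix_cols=48, n_slices=5)


@pytest.fixture(scope="session")
def small_phantom(small_params):
    return generate_phantom(small_params, seed=1, n_roi_slices=3)


@pytest.fixture()
def noiseless_config():
    return SyntheticStudyConfig(
        groups=default_groups(), n_per_group=2, noise_model="none", noise_sigma=0.0,
        seed=11,
    )
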