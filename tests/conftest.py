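import numpy as np
import pytest

from anthosense.synthetic import (default_emission_design,
                                  default_spectra_design,
                                  default_visit_design, gen_emission_matrix,
                                  gen_reflectance_set, gen_visit_log)


@pytest.fixture(scope="session")
def spectra_noisefree():
    """Seven flowers x three parts, noise-free archetype curves."""
    return gen_reflectance_set(default_spectra_design(seed=0, noise_sd=0.0))


@pytest.fixture(scope="session")
def spectra_noisy():
    return gen_reflectance_set(default_spectra_design(seed=1, noise_sd=0.01))


@pytest.fixture(scope="session")
def emissions_default():
    """Intrafloral emission matrix with the default part effects."""
    return gen_emission_matrix(default_emission_design(seed=3))


@pytest.fixture(scope="session")
def visit_log_default():
    design = default_visit_design(seed=0)
    return gen_visit_log(design), design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
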