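import numpy as np
import pytest

from muellermc import mie


@pytest.fixture(scope="session")
def phase_table():
    """Ensemble phase table of the five-group 50 nm sphere mixture at
    633 nm in the n = 1.33 host, scaled to mu_s = 400 cm^-1."""
    groups = mie.density_for_target_mus(
        mie.gaussian_size_groups(), 633.0, 1.33, 400.0
    )
    return mie.build_phase_table(groups, 633.0, 1.33)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240633)
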