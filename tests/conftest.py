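import numpy as np
import pytest

from ramansort import synthetic as syn


@pytest.fixture(scope="session")
def axis():
    return syn.SpectrumAxis()


@pytest.fixture(scope="session")
def grid(axis):
    return axis.grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def labeled_cell(axis):
    """A noiseless heavy-water-labeled cell with analytic CDR 2/11."""
    bands = [syn.BandModel(2157, 40, 1.0), syn.BandModel(2930, 60, 3.0)]
    return syn.make_spectrum(axis, bands, noise_sd=0.0, seed=0)
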