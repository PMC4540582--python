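import numpy as np
import pytest

from ncbind.energy import ModelParams, sample_binder_ensemble


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def default_ensemble(default_params):
    return sample_binder_ensemble(default_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n, p=None):
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
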