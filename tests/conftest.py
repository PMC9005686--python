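import numpy as np
import pytest

from femorph.landmarks import small_scheme
from femorph.synthetic import default_truth, make_template, simulate_sample


@pytest.fixture(scope="session")
def scheme():
    return small_scheme()


@pytest.fixture(scope="session")
def template(scheme):
    return make_template(scheme)


@pytest.fixture(scope="session")
def synthetic_sample():
    """A 36-taxon study-condition sample with its ground truth."""
    truth = default_truth(n_tips=36, seed=17)
    configs, records = simulate_sample(truth)
    return truth, configs, records


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
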