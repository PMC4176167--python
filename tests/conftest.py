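import numpy as np
import pytest

from mbdex.exchange import ExchangeModel
from mbdex.synthetic import gen_ensemble, synthetic_template


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def symmetric_model():
    """Symmetric two-site model with a 40 ms site lifetime."""
    return ExchangeModel(k_ab=25.0, k_ba=25.0, r1_a=2.0, r1_b=2.0, i0_a=1.0, i0_b=1.0)


@pytest.fixture(scope="session")
def template():
    return synthetic_template()


@pytest.fixture(scope="session")
def jittered_ensemble(template):
    return gen_ensemble(template=template, n_models=20, jitter_a=0.5, seed=7)
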