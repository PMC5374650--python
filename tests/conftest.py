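import numpy as np
import pytest

from rdhill import build_toy_model, toy_params


@pytest.fixture(scope="session")
def params25():
    return toy_params(K_m=25.0)


@pytest.fixture(scope="session")
def params50():
    return toy_params(K_m=50.0)


@pytest.fixture()
def toy_k5():
    """A small smoothed toy model plus a mixed initial state."""
    model = build_toy_model(K=5, K_m=25.0, smoothing="fixed:3")
    initial = model.initial_state({"E": 25, "P": 10})
    return model, initial


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20171403)
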