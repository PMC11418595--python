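import numpy as np
import pytest

import mmirtree as mt


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def random_items(rng):
    """Random valid item parameters for 6 items."""
    J = 6
    aers = np.zeros((J, 4))
    amrs = np.zeros((J, 4))
    aers[:, [0, 2]] = rng.uniform(0.75, 1.25, size=(J, 2))
    amrs[:, [1, 2]] = rng.uniform(0.50, 0.75, size=(J, 2))
    return mt.ItemParameters(
        alpha_theta=rng.uniform(0.75, 1.75, size=J),
        omega=0.5,
        alpha_ers=aers,
        alpha_mrs=amrs,
        beta=rng.uniform(-2, 2, size=(J, 3, 4)),
    )


@pytest.fixture(scope="session")
def random_persons(rng):
    R = np.array([[1.0, 0.2, 0.0], [0.2, 1.0, -0.4], [0.0, -0.4, 1.0]])
    u = rng.multivariate_normal(np.zeros(3), R, size=12)
    return mt.PersonParameters(u[:, 0], u[:, 1], u[:, 2], R)


@pytest.fixture(scope="session")
def mixture_fixture():
    """Tiny deterministic mixture dataset with ground truth."""
    return mt.make_fixture("mixture_small", seed=5)
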