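import numpy as np
import pytest

from shellopt import NoiseModel, decompose, make_shell_means, neonatal_like_preset


def random_orthonormal(n_shells, rng):
    """Random orthonormal basis via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(n_shells, n_shells)))
    return q * np.sign(np.diag(r))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def neonatal_data():
    """Shell-mean matrix from the neonatal-like phantom preset."""
    data, truth = make_shell_means(neonatal_like_preset(seed=11))
    return data, truth


@pytest.fixture(scope="session")
def neonatal_basis(neonatal_data):
    data, _ = neonatal_data
    return decompose(data)


@pytest.fixture(scope="session")
def neonatal_noise(neonatal_data):
    data, _ = neonatal_data
    return NoiseModel.from_snr(30.0, float(data.D[0].mean()))
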