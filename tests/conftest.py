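import numpy as np
import pytest

from snchamp.model_core import LeadField, NoiseModel, SensorDataset


def random_problem(rng, m=None, n=None, K=None, noise_scale=0.1):
    """Small random (data, leadfield, noise) triple for oracle tests."""
    m = m or int(rng.integers(2, 7))
    n = n or int(rng.integers(2, 11))
    K = K or int(rng.integers(2, 21))
    L = rng.standard_normal((m, n))
    L /= np.linalg.norm(L, axis=0)
    lf = LeadField(L, rng.uniform(0, 50, size=(n, 3)), normalized=True)
    data = SensorDataset(rng.standard_normal((m, K)), fs=1000.0)
    noise = NoiseModel(noise_scale * np.eye(m))
    return data, lf, noise


def random_spd(rng, m):
    a = rng.standard_normal((m, m))
    return a @ a.T + m * np.eye(m)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
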