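import numpy as np
import pytest

from quathar import ReferenceFields, SensorNoiseModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fields():
    return ReferenceFields()


@pytest.fixture
def noiseless():
    return SensorNoiseModel.noiseless()


def random_unit_quaternions(rng, n):
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)
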