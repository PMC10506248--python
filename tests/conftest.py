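import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bcseg.phantoms import PhantomSpec, gen_abdomen, gen_liver, gen_thigh
from bcseg.types import SliceType


@pytest.fixture(scope="session")
def thigh_sample():
    return gen_thigh(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def thigh_sample_noiseless():
    return gen_thigh(PhantomSpec(seed=11).noiseless())


@pytest.fixture(scope="session")
def abdomen_sample():
    return gen_abdomen(PhantomSpec(slice_type=SliceType.ABDOMEN, seed=11))


@pytest.fixture(scope="session")
def liver_sample():
    return gen_liver(PhantomSpec(slice_type=SliceType.LIVER, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
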