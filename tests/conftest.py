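import numpy as np
import pytest

from dbpstack import FixtureSpec, gen_benchmark, gen_pssm, gen_struct_profile
from dbpstack.sequence_io import ProteinRecord


@pytest.fixture(scope="session")
def small_benchmark():
    """Separable synthetic benchmark: 60 + 60 records, full class signal."""
    spec = FixtureSpec(n_pos=60, n_neg=60, length_range=(51, 90), seed=11,
                       signal_strength=1.0)
    return gen_benchmark(spec)


@pytest.fixture(scope="session")
def toy_record():
    return ProteinRecord("toy", "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
                                "ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture(scope="session")
def toy_pssm(toy_record):
    return gen_pssm(toy_record, seed=3, strength=0.8)


@pytest.fixture(scope="session")
def toy_struct(toy_record):
    return gen_struct_profile(toy_record, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
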