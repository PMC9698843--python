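import numpy as np
import pytest
from hypothesis import settings

from p25scan import ProteinSeq, make_fungal_type_protein

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def fungal_protein():
    """One deterministic synthetic fungal-type TPPP plus its domain truth."""
    return make_fungal_type_protein(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, n, record_id="p"):
    return ProteinSeq(record_id, "".join(rng.choice(list(AA20), size=n)))
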