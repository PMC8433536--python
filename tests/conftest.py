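import logging

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from oxosig.synthetic import make_reference, pseudo_signature_matrix
from oxosig.variant_io import ReferenceContextSource

logging.getLogger("oxosig").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def reference_path(tmp_path_factory):
    path = tmp_path_factory.mktemp("ref") / "reference.fa"
    make_reference(path, n_chroms=2, length=120_000, seed=424242)
    return path


@pytest.fixture(scope="session")
def reference(reference_path):
    return ReferenceContextSource(reference_path)


@pytest.fixture(scope="session")
def matrix():
    return pseudo_signature_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
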