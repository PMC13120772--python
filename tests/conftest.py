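import numpy as np
import pytest
from hypothesis import settings

from ghannot.synthetic import SyntheticDesign, generate_query_set, generate_reference_db

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design():
    """Compact separable design used by most unit tests."""
    return SyntheticDesign(
        n_families=2,
        clusters_per_family=2,
        members_per_cluster=4,
        sequence_length=160,
        n_decoys=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_db(small_design):
    bundle, truths = generate_reference_db(small_design)
    return bundle, truths


@pytest.fixture(scope="session")
def small_bundle(small_db):
    return small_db[0]


@pytest.fixture(scope="session")
def small_queries(small_bundle):
    rng = np.random.default_rng(23)
    return generate_query_set(
        small_bundle,
        {"cluster_assigned": 8, "cluster_undefined": 2, "unannotated": 2},
        rng=rng,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
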