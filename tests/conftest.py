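import numpy as np
import pytest
from hypothesis import settings

import nano16s as n16

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_db():
    """Four well-separated synthetic 16S reference taxa."""
    return n16.make_reference_db(4, seq_length=1500, divergence=0.1, seed=101)


@pytest.fixture(scope="session")
def scheme_2bc():
    """An 8-sample 2BC scheme in one native pool."""
    return n16.make_scheme(8, mode="2BC", seed=102)


@pytest.fixture(scope="session")
def scheme_1bc():
    return n16.make_scheme(4, mode="1BC", seed=103)


@pytest.fixture(scope="session")
def noiseless_pool(scheme_2bc, small_db):
    """8 samples x 100 error-free reads with truth sidecar."""
    records, truth = n16.simulate_pool(
        scheme_2bc, small_db, 100, n16.ErrorModel.noiseless(), seed=104
    )
    return records, truth


def make_profile(abunds: dict[str, float], total_reads: int = 100) -> n16.AbundanceProfile:
    return n16.AbundanceProfile(
        "sample",
        {t: (a, a * total_reads) for t, a in abunds.items()},
        total_reads,
    )
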