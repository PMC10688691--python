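import numpy as np
import pytest

from ipdssr import CensoringScheme, PFFCSample, load_fixture


def complete_sample(values) -> PFFCSample:
    """Wrap plain values as a complete sample (k=1, no removals)."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    scheme = CensoringScheme(n_groups=n, k_per_group=1, m_failures=n,
                             removals=(0,) * n)
    return PFFCSample(values, scheme)


@pytest.fixture(scope="session")
def jute():
    return load_fixture("jute")


@pytest.fixture(scope="session")
def insulation():
    return load_fixture("insulation")


@pytest.fixture
def toy_sample():
    """Single observation at x=1 with k=1 and no removals: F(1) = 2**-alpha."""
    scheme = CensoringScheme(n_groups=1, k_per_group=1, m_failures=1, removals=(0,))
    return PFFCSample(np.array([1.0]), scheme)
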