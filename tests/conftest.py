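import numpy as np
import pytest

from neutralsad import CommunitySample


def integer_partitions(J):
    """All integer partitions of J as abundance lists (independent oracle:
    sympy's partition iterator, not the package's own combinatorics)."""
    from sympy.utilities.iterables import partitions

    for p in partitions(J):
        yield [a for a, c in p.items() for _ in range(c)]


@pytest.fixture(scope="session")
def partition_sads():
    """CommunitySamples for every partition of J, J = 1..8, keyed by J."""
    return {
        J: [CommunitySample.from_counts(p) for p in integer_partitions(J)]
        for J in range(1, 9)
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20161608)
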