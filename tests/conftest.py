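import numpy as np
import pytest

from ultrafa import (
    Hierarchy,
    UltrametricValues,
    compose_ultrametric,
    generate_structure,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_group_hierarchy():
    """J=4: groups {V1,V2} and {V3,V4}, one merge."""
    return Hierarchy([1, 1, 2, 2], [(1, 2)])


@pytest.fixture
def two_group_values():
    return UltrametricValues([0.7, 0.6], [0.3])


@pytest.fixture
def two_group_matrix(two_group_hierarchy, two_group_values):
    return compose_ultrametric(two_group_hierarchy, two_group_values)


@pytest.fixture
def planted_12_3():
    """Exactly ultrametric J=12, Q=3 problem with its generating parameters."""
    truth = generate_structure(12, 3, rng=7)
    from ultrafa import generate_sigma

    return truth, generate_sigma(truth)


def corr(offdiag):
    """3x3 correlation matrix with given off-diagonals (r12, r13, r23)."""
    r12, r13, r23 = offdiag
    return np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
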