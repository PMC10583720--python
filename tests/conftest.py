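import numpy as np
import pytest

from crossfx.distributions import BinaryDataset, ObservedDistribution
from crossfx.lp_bounds import marginalize_q
from crossfx.synthetic_data import dataset_from_cell_counts, unconfounded_q


@pytest.fixture
def uniform_dist() -> ObservedDistribution:
    """All 16 probabilities equal to 1/8 (uniform within each arm)."""
    return ObservedDistribution(np.full((2, 2, 2, 2), 0.125))


@pytest.fixture
def point_mass_dist() -> ObservedDistribution:
    """Point mass on (Y=1, M1=0, M2=0) in both arms: Y is constant."""
    p = np.zeros((2, 2, 2, 2))
    p[1, 0, 0, 0] = 1.0
    p[1, 0, 0, 1] = 1.0
    return ObservedDistribution(p)


@pytest.fixture
def uniform_dataset() -> BinaryDataset:
    """One record per (y, m1, m2) pattern in each arm: the uniform table."""
    counts = np.ones((2, 2, 2, 2), dtype=int)
    return dataset_from_cell_counts(counts)


@pytest.fixture
def npsem_dataset():
    """A moderate unconfounded variant-B dataset with its exact table."""
    q = unconfounded_q("B", seed=2)
    dist = marginalize_q(q)
    counts = np.round(dist.p * 4096).astype(int)
    # not exactly rational; used only where sampling error is irrelevant
    return dataset_from_cell_counts(counts), q
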