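import numpy as np
import pytest

import hospgroups as hg


@pytest.fixture
def toy_od():
    """2 facilities x 3 units with hand-checkable totals."""
    return hg.UtilizationOD(
        facilities=["A", "B"],
        units=["z1", "z2", "z3"],
        counts=np.array([[10.0, 30.0, 10.0], [5.0, 5.0, 40.0]]),
    )


@pytest.fixture
def toy_dist():
    return hg.DistanceMatrix(
        facilities=["A", "B"],
        d=np.array([[0.0, 4.0], [4.0, 0.0]]),
    )


@pytest.fixture
def strong_region():
    """A strongly separated planted-community region (generator defaults)."""
    return hg.generate_region(hg.SyntheticConfig(seed=7))


@pytest.fixture
def strong_features(strong_region):
    ci = hg.compute_ci(strong_region.od)
    return hg.features_from(ci, strong_region.dist)


def random_od(rng, n=5, z=8):
    """Random OD fixture with every facility active."""
    counts = rng.integers(0, 50, size=(n, z)).astype(float)
    counts[:, 0] += 1  # guarantee nonzero facility totals
    return hg.UtilizationOD(
        facilities=[f"F{i}" for i in range(n)],
        units=[f"U{j}" for j in range(z)],
        counts=counts,
    )
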