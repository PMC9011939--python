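import numpy as np
import pytest

from polyview import SpatialSample


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_sample(
    n_units: int = 20,
    n_markers: int = 3,
    seed: int = 0,
    celltype: bool = False,
    side: float = 10.0,
) -> SpatialSample:
    """Small random sample with uniform positions and N(0,1) expression."""
    rng = np.random.default_rng(seed)
    types = ["ct0", "ct1", "ct2", "ct3"]
    return SpatialSample(
        positions=rng.uniform(0, side, size=(n_units, 2)),
        expression=rng.normal(size=(n_units, n_markers)),
        markers=[f"m{i}" for i in range(n_markers)],
        celltype=(
            [types[i % 4] for i in range(n_units)] if celltype else None
        ),
    )


@pytest.fixture
def small_sample():
    return make_sample(n_units=20, n_markers=3, seed=1)
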