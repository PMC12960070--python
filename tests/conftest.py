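import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ionclust as ic

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_sizes(rng: np.random.Generator, n_ions: int = 44, max_size: int = 4):
    """Random multiset of cluster sizes summing to ``n_ions``."""
    sizes = []
    remaining = n_ions
    while remaining > 0:
        k = int(rng.integers(1, min(max_size, remaining) + 1))
        sizes.append(k)
        remaining -= k
    return tuple(sizes)


def members(partition: ic.ClusterPartition) -> set[frozenset]:
    return {frozenset(c.member_ids) for c in partition.clusters}


@pytest.fixture(scope="session")
def planted_44():
    """One moderately rich 44-ion planted frame with solvent."""
    spec = ic.PlantedSpec(sizes=(4, 3, 3, 2, 2, 2, 1) + (1,) * 27, seed=11)
    frame, truth = ic.plant_frame(spec)
    return spec, frame, truth


@pytest.fixture(scope="session")
def small_planted():
    """A small frame (7 ions, sizes 1,1,2,3) for cheap per-test scans."""
    spec = ic.PlantedSpec(sizes=(3, 2, 1, 1), n_cations=4, n_anions=3, seed=5)
    frame, truth = ic.plant_frame(spec)
    return spec, frame, truth
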