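import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import motupipe as mp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_design():
    """Full hierarchical design (3 regions, 3/5/3 sites, 3 plots)."""
    spec = mp.DesignSpec(seed=11)
    samples, env = mp.generate_design(spec)
    return spec, samples, env


@pytest.fixture(scope="session")
def small_community(small_design):
    """A modest community on the full design, with reduced depths so the
    dataset stays light for clustering-level tests."""
    _, samples, env = small_design
    spec = mp.CommunitySpec(pool_size=200)
    reference, abundance = mp.generate_community(
        spec,
        samples,
        env,
        seed=11,
        depth_ranges={"leaf": (700, 1500), "root": (552, 1200)},
    )
    return spec, reference, abundance


def random_counts(rng: np.random.Generator, n_motus: int, max_count: int = 40):
    """Random sparse count vector with some singletons and zeros."""
    counts = rng.integers(0, max_count, size=n_motus)
    counts[rng.random(n_motus) < 0.3] = 0
    counts[rng.random(n_motus) < 0.2] = 1
    return counts


def binary_matrix(rng: np.random.Generator, n: int, m: int, p: float = 0.4):
    X = (rng.random((n, m)) < p).astype(np.int8)
    X[X.sum(axis=1) == 0, 0] = 1
    X = X[:, X.sum(axis=0) > 0]
    return pd.DataFrame(X, index=[f"s{i}" for i in range(n)])
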