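import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TINY_MODULE_SIZES = (5, 4, 5, 4, 3, 3)


@pytest.fixture(scope="session")
def tiny_spec():
    """A fast, structurally faithful miniature cohort specification."""
    import fcgraph as fg

    return fg.CohortSpec(
        n_patients=5,
        n_controls=6,
        n_rois=24,
        n_frames=60,
        module_sizes=TINY_MODULE_SIZES,
        master_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    import fcgraph as fg

    return fg.generate_cohort(tiny_spec)


@pytest.fixture
def triangle_pendant():
    """Triangle a-b-c plus pendant edge d-a."""
    adj = np.zeros((4, 4), dtype=np.uint8)
    for i, j in [(0, 1), (0, 2), (1, 2), (0, 3)]:
        adj[i, j] = adj[j, i] = 1
    return adj


def random_simple_graph(rng: np.random.Generator, n_max: int = 8) -> np.ndarray:
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.15, 0.9))
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return (adj | adj.T).astype(np.uint8)
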