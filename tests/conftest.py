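import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import blockrec as br

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_dataset() -> br.RatingDataset:
    """3 ratings, 2 users x 2 items, K=2 — the smallest interesting network."""
    return br.build_dataset([("A", "x", 1), ("A", "y", 2), ("B", "x", 1)], K=2)


@pytest.fixture
def random_dataset() -> br.RatingDataset:
    """A fixed 5x4, K=3 dataset with 12 of 20 pairs observed."""
    rng = np.random.default_rng(42)
    pairs = [(u, i) for u in range(5) for i in range(4)]
    chosen = rng.choice(len(pairs), 12, replace=False)
    triples = [(pairs[k][0], pairs[k][1], int(rng.integers(1, 4))) for k in chosen]
    return br.build_dataset(triples, K=3, n_users=5, n_items=4)


def random_partition(dataset: br.RatingDataset, rng: np.random.Generator) -> br.Partition:
    return br.Partition(
        rng.integers(0, dataset.n_users, size=dataset.n_users),
        rng.integers(0, dataset.n_items, size=dataset.n_items),
    )
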