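"""Block-structured synthetic like/dislike ratings with planted ground truth.

Each item i carries an intrinsic quality Q_i ~ Uniform(0,1); users and items
are planted into groups and each (user-group, item-group) block carries an
a-priori preference pi ~ Uniform(0,1).  The probability that user u likes
item i (class 1, as opposed to class 2, dislike) interpolates between the
two factors:

    p_like(u, i) = (1 - lambda) * Q_i + lambda * pi[sigma_u, tau_i]

At lambda = 0 the item's quality is the only relevant factor — the naive
per-item average is then the optimal predictor; at lambda = 1 block
preferences are the only factor, the per-item average rating carries no
signal, and block-model inference dominates.  To realize that regime the
default pi draw is i.i.d. Uniform(0,1) recentered so that every item
group's average preference across user groups is exactly one half (clipped
to [0,1]): without the recentering an item's mean rating would still
reflect its group's average preference and the naive recommender would
remain informative at lambda = 1.  The generator also reports the
Bayes-optimal accuracy E[max(p, 1-p)] that any algorithm could at best
attain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import RatingDataset, build_dataset

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "optimal_accuracy",
    "make_fixture",
    "Fixture",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic benchmark.

    Defaults match the dichotomous benchmark protocol: 100 users and 100
    items in 5 planted groups per side, 4,000 observed ratings and 1,000
    test ratings.  ``pi`` optionally overrides the Uniform(0,1) draw of the
    per-block preferences (e.g. to plant well-separated blocks).
    """

    n_users: int = 100
    n_items: int = 100
    n_user_groups: int = 5
    n_item_groups: int = 5
    lam: float = 0.5
    n_observed: int = 4000
    n_test: int = 1000
    seed: int = 0
    pi: np.ndarray | None = None

    def validate(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")
        if self.n_user_groups > self.n_users or self.n_item_groups > self.n_items:
            raise ValueError("more planted groups than nodes")
        if self.n_observed + self.n_test > self.n_users * self.n_items:
            raise ValueError(
                f"pair budget {self.n_observed}+{self.n_test} exceeds "
                f"{self.n_users * self.n_items} available pairs"
            )
        if self.pi is not None and np.asarray(self.pi).shape != (
            self.n_user_groups,
            self.n_item_groups,
        ):
            raise ValueError("pi must have shape (n_user_groups, n_item_groups)")


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic realization."""

    user_groups: np.ndarray  # (n_users,) planted labels
    item_groups: np.ndarray  # (n_items,)
    quality: np.ndarray  # (n_items,) Q_i in [0, 1]
    pi: np.ndarray  # (n_user_groups, n_item_groups) in [0, 1]
    lam: float

    def p_like(self, users: np.ndarray, items: np.ndarray) -> np.ndarray:
        """True probability of class 1 for each (user, item) pair."""
        block = self.pi[self.user_groups[users], self.item_groups[items]]
        return (1.0 - self.lam) * self.quality[items] + self.lam * block


def generate(
    config: GeneratorConfig,
) -> tuple[RatingDataset, list[tuple[int, int, int]], GroundTruth]:
    """Draw one synthetic realization.

    Returns the training :class:`RatingDataset` (K = 2, class 1 = like),
    the held-out test triples, and the planted :class:`GroundTruth`.
    Training and test pairs are distinct, sampled uniformly without
    replacement from the full user x item grid.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    user_groups = rng.integers(0, config.n_user_groups, size=config.n_users)
    item_groups = rng.integers(0, config.n_item_groups, size=config.n_items)
    quality = rng.uniform(size=config.n_items)
    if config.pi is None:
        pi = rng.uniform(size=(config.n_user_groups, config.n_item_groups))
        # balance each item group's preferences so the item-mean signal
        # vanishes at lambda = 1 (naive recommender uninformative there)
        pi = np.clip(pi - pi.mean(axis=0, keepdims=True) + 0.5, 0.0, 1.0)
    else:
        pi = np.asarray(config.pi, dtype=float)
    truth = GroundTruth(user_groups, item_groups, quality, pi, config.lam)

    n_pairs = config.n_observed + config.n_test
    flat = rng.choice(config.n_users * config.n_items, size=n_pairs, replace=False)
    users, items = np.divmod(flat, config.n_items)
    p = truth.p_like(users, items)
    classes = np.where(rng.uniform(size=n_pairs) < p, 1, 2)

    train = [
        (int(users[k]), int(items[k]), int(classes[k])) for k in range(config.n_observed)
    ]
    test = [
        (int(users[k]), int(items[k]), int(classes[k]))
        for k in range(config.n_observed, n_pairs)
    ]
    dataset = build_dataset(train, K=2, n_users=config.n_users, n_items=config.n_items)
    return dataset, test, truth


def optimal_accuracy(
    truth: GroundTruth,
    test_triples: Sequence[tuple[int, int, int]],
) -> tuple[float, float]:
    """Accuracy ceiling of a predictor that knows the true probabilities.

    Returns ``(expected, realized)``: the expected accuracy
    mean(max(p, 1-p)) of the Bayes-optimal rule, and the realized accuracy
    of its argmax predictions against the sampled labels (ties at p = 1/2
    predict class 1).
    """
    users = np.array([t[0] for t in test_triples])
    items = np.array([t[1] for t in test_triples])
    labels = np.array([t[2] for t in test_triples])
    p = truth.p_like(users, items)
    expected = float(np.mean(np.maximum(p, 1.0 - p)))
    realized = float(np.mean(np.where(p >= 0.5, 1, 2) == labels))
    return expected, realized


@dataclass
class Fixture:
    """A small deterministic dataset plus its known held-out answers."""

    dataset: RatingDataset
    heldout: list[tuple[int, int, int]]  # (user, item, expected class)


def make_fixture(name: str) -> Fixture:
    """Hard-coded regression fixtures.

    ``"blocks-2x2"``: 8 users x 8 items in 2x2 blocks, each block rated with
    one constant class (K = 2) and a few entries withheld — the
    high-explanatory-power partition is known by construction, so block-model
    inference must predict each withheld entry as its block's constant.
    ``"empty"``: 2 users x 2 items, no ratings.  ``"single"``: one user, one
    item, one class-1 rating.
    """
    if name == "blocks-2x2":
        block_class = np.array([[1, 2], [2, 1]])  # user-block x item-block
        withheld = {(0, 1), (2, 6), (5, 3), (7, 7), (4, 0)}
        triples = []
        heldout = []
        for u in range(8):
            for i in range(8):
                r = int(block_class[u // 4, i // 4])
                if (u, i) in withheld:
                    heldout.append((u, i, r))
                else:
                    triples.append((u, i, r))
        return Fixture(build_dataset(triples, K=2, n_users=8, n_items=8), heldout)
    if name == "empty":
        return Fixture(build_dataset([], K=2, n_users=2, n_items=2), [])
    if name == "single":
        return Fixture(build_dataset([(0, 0, 1)], K=2, n_users=1, n_items=1), [])
    raise ValueError(f"unknown fixture {name!r}")
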