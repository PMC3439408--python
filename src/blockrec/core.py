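"""Core data structures and the marginalized block-model Hamiltonian.

A bipartite rating network connects users to items with labeled links
(integer rating classes ``1..K``).  Under a stochastic block model, users
and items are simultaneously partitioned into groups and the probability of
each rating class depends only on the (user-group, item-group) pair.
Integrating the per-block class probabilities over the simplex with a flat
prior yields a Dirichlet-multinomial marginal likelihood per block; its
negative logarithm is the Hamiltonian implemented here.  Everything is kept
in log-space via ``lgamma`` because rating counts can reach 1e5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma
from typing import Hashable, Iterable, Sequence

import numpy as np

__all__ = [
    "RatingDataset",
    "Partition",
    "BlockCountTable",
    "build_dataset",
    "count_blocks",
    "hamiltonian",
    "labeled_sampling_correction",
    "move_delta",
    "Move",
]


# ---------------------------------------------------------------------------
# Datasets


@dataclass
class RatingDataset:
    """Bipartite multiclass-labeled link set with dense internal indexing.

    Observed ratings are stored as parallel arrays ``users``, ``items``
    (0-based internal indices) and ``ratings`` (classes ``1..K``).  External
    identifiers round-trip through ``user_ids`` / ``item_ids`` and the
    inverse lookup maps.  Isolated nodes (no ratings) are allowed: any index
    in ``[0, n_users)`` x ``[0, n_items)`` is a valid query.
    """

    n_users: int
    n_items: int
    K: int
    users: np.ndarray
    items: np.ndarray
    ratings: np.ndarray
    user_ids: list = field(default_factory=list)
    item_ids: list = field(default_factory=list)
    user_index: dict = field(default_factory=dict)
    item_index: dict = field(default_factory=dict)

    @property
    def n_observed(self) -> int:
        return len(self.ratings)

    def triples(self) -> Iterable[tuple[Hashable, Hashable, int]]:
        """Yield observed ratings with external identifiers."""
        for u, i, r in zip(self.users, self.items, self.ratings):
            yield self.user_ids[u], self.item_ids[i], int(r)

    def user_of(self, external_id: Hashable) -> int:
        try:
            return self.user_index[external_id]
        except KeyError:
            raise KeyError(f"unknown user id {external_id!r}") from None

    def item_of(self, external_id: Hashable) -> int:
        try:
            return self.item_index[external_id]
        except KeyError:
            raise KeyError(f"unknown item id {external_id!r}") from None

    def adjacency(self) -> tuple[np.ndarray, ...]:
        """CSR-style adjacency for both sides.

        Returns ``(u_ptr, u_items, u_ratings, i_ptr, i_users, i_ratings)``
        with ratings stored 0-based (class ``r`` at slot ``r - 1``), the
        layout the sampler kernel consumes.
        """
        order = np.argsort(self.users, kind="stable")
        u_ptr = np.zeros(self.n_users + 1, dtype=np.int64)
        np.add.at(u_ptr[1:], self.users, 1)
        np.cumsum(u_ptr, out=u_ptr)
        u_items = self.items[order].astype(np.int64)
        u_ratings = (self.ratings[order] - 1).astype(np.int64)

        order = np.argsort(self.items, kind="stable")
        i_ptr = np.zeros(self.n_items + 1, dtype=np.int64)
        np.add.at(i_ptr[1:], self.items, 1)
        np.cumsum(i_ptr, out=i_ptr)
        i_users = self.users[order].astype(np.int64)
        i_ratings = (self.ratings[order] - 1).astype(np.int64)
        return u_ptr, u_items, u_ratings, i_ptr, i_users, i_ratings


def build_dataset(
    triples: Sequence[tuple[Hashable, Hashable, int]],
    K: int,
    n_users: int | None = None,
    n_items: int | None = None,
) -> RatingDataset:
    """Assemble a :class:`RatingDataset` from (user id, item id, class) triples.

    Dense internal indices are assigned in first-appearance order.  When
    ``n_users`` / ``n_items`` are given and external ids are integers in
    ``[0, n)``, identity indexing is used so that isolated nodes exist.

    Raises
    ------
    ValueError
        If a (user, item) pair occurs twice or a class lies outside ``1..K``.
    """
    if K < 2:
        raise ValueError(f"need at least two rating classes, got K={K}")
    identity = n_users is not None and n_items is not None
    user_ids: list = list(range(n_users)) if identity else []
    item_ids: list = list(range(n_items)) if identity else []
    user_index: dict = {u: u for u in user_ids}
    item_index: dict = {i: i for i in item_ids}
    users, items, ratings = [], [], []
    seen: set[tuple[int, int]] = set()
    for uid, iid, r in triples:
        r = int(r)
        if not 1 <= r <= K:
            raise ValueError(f"rating class {r} out of range 1..{K} in triple ({uid!r}, {iid!r}, {r})")
        if uid not in user_index:
            if identity:
                raise ValueError(f"user id {uid!r} outside declared range [0, {n_users})")
            user_index[uid] = len(user_ids)
            user_ids.append(uid)
        if iid not in item_index:
            if identity:
                raise ValueError(f"item id {iid!r} outside declared range [0, {n_items})")
            item_index[iid] = len(item_ids)
            item_ids.append(iid)
        u, i = user_index[uid], item_index[iid]
        if (u, i) in seen:
            raise ValueError(f"duplicate rating for pair ({uid!r}, {iid!r})")
        seen.add((u, i))
        users.append(u)
        items.append(i)
        ratings.append(r)
    return RatingDataset(
        n_users=len(user_ids),
        n_items=len(item_ids),
        K=K,
        users=np.asarray(users, dtype=np.int64),
        items=np.asarray(items, dtype=np.int64),
        ratings=np.asarray(ratings, dtype=np.int64),
        user_ids=user_ids,
        item_ids=item_ids,
        user_index=user_index,
        item_index=item_index,
    )


# ---------------------------------------------------------------------------
# Partitions


@dataclass
class Partition:
    """Simultaneous grouping of users and items; the sampler's state.

    Group labels are 0-based integers drawn from a label space of one label
    per node (so a side with ``N`` nodes has ``N`` admissible labels, most
    of them unused in any given partition).
    """

    user_assignment: np.ndarray
    item_assignment: np.ndarray

    def __post_init__(self) -> None:
        self.user_assignment = np.asarray(self.user_assignment, dtype=np.int64)
        self.item_assignment = np.asarray(self.item_assignment, dtype=np.int64)
        n_u, n_i = len(self.user_assignment), len(self.item_assignment)
        for name, a, n in (
            ("user", self.user_assignment, n_u),
            ("item", self.item_assignment, n_i),
        ):
            if len(a) and (a.min() < 0 or a.max() >= n):
                raise ValueError(f"{name} group labels must lie in [0, {n})")

    @property
    def n_users(self) -> int:
        return len(self.user_assignment)

    @property
    def n_items(self) -> int:
        return len(self.item_assignment)

    @property
    def g_users(self) -> int:
        return len(np.unique(self.user_assignment))

    @property
    def g_items(self) -> int:
        return len(np.unique(self.item_assignment))

    def copy(self) -> "Partition":
        return Partition(self.user_assignment.copy(), self.item_assignment.copy())


def canonical_labels(assignment: np.ndarray) -> tuple[int, ...]:
    """Restricted-growth normal form: relabel groups in first-appearance order.

    Two assignments describe the same unlabeled partition iff their
    canonical forms coincide.
    """
    mapping: dict[int, int] = {}
    out = []
    for g in assignment:
        g = int(g)
        if g not in mapping:
            mapping[g] = len(mapping)
        out.append(mapping[g])
    return tuple(out)


# ---------------------------------------------------------------------------
# Block counts and the Hamiltonian


@dataclass
class BlockCountTable:
    """Per-block rating-class counts, the Hamiltonian's sufficient statistics.

    ``counts[a, b, r - 1]`` is the number of class-``r`` ratings between
    user-group ``a`` and item-group ``b``; ``totals`` sums over classes.
    Stored dense over the full label space so single-node moves touch only
    one row/column.
    """

    counts: np.ndarray  # (n_user_labels, n_item_labels, K) int64

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=2)

    @property
    def K(self) -> int:
        return self.counts.shape[2]

    def validate(self, n_observed: int | None = None) -> None:
        if (self.counts < 0).any():
            raise ValueError("negative block counts")
        if n_observed is not None and int(self.counts.sum()) != n_observed:
            raise ValueError(
                f"block counts sum to {int(self.counts.sum())}, expected {n_observed}"
            )


def count_blocks(dataset: RatingDataset, partition: Partition) -> BlockCountTable:
    """Tally ``n^r_{ab}`` for every (user-group, item-group, class) cell."""
    if partition.n_users != dataset.n_users or partition.n_items != dataset.n_items:
        raise ValueError(
            f"partition covers {partition.n_users}x{partition.n_items} nodes, "
            f"dataset has {dataset.n_users}x{dataset.n_items}"
        )
    counts = np.zeros((dataset.n_users, dataset.n_items, dataset.K), dtype=np.int64)
    if dataset.n_observed:
        np.add.at(
            counts,
            (
                partition.user_assignment[dataset.users],
                partition.item_assignment[dataset.items],
                dataset.ratings - 1,
            ),
            1,
        )
    return BlockCountTable(counts)


def hamiltonian(counts: BlockCountTable, K: int | None = None) -> float:
    """Minus log marginal likelihood of a partition pair (up to a constant).

    For each block, integrating the K class probabilities over the simplex
    under a flat prior gives ``(K-1)! prod_r n^r! / (n + K - 1)!``, so

        H = sum_blocks [ lnGamma(n + K) - sum_r lnGamma(n^r + 1) - lnGamma(K) ].

    Empty blocks contribute exactly zero, which makes H insensitive to how
    many unused labels the storage carries.  Lower H = more explanatory
    power.
    """
    c = counts.counts
    if K is None:
        K = c.shape[2]
    elif K != c.shape[2]:
        raise ValueError(f"table has {c.shape[2]} classes, K={K} requested")
    counts.validate()
    totals = c.sum(axis=2)
    mask = totals > 0
    if not mask.any():
        return 0.0
    from scipy.special import gammaln

    h = gammaln(totals[mask] + K) - gammaln(c[mask] + 1).sum(axis=1) - gammaln(K)
    return float(h.sum())


def labeled_sampling_correction(
    partition: Partition,
    n_users: int | None = None,
    n_items: int | None = None,
) -> float:
    """Log over-counting factor of labeled-group sampling.

    With a label space of one label per node, a partition with ``g``
    non-empty groups on a side of ``N`` nodes is realized by ``N!/(N-g)!``
    distinct labelings.  The sampler therefore targets ``exp(-(H + C))``
    with ``C = ln N_U!/(N_U-g_U)! + ln N_I!/(N_I-g_I)!`` so that unlabeled
    partitions are weighted by ``exp(-H)`` alone.
    """
    n_u = partition.n_users if n_users is None else n_users
    n_i = partition.n_items if n_items is None else n_items
    g_u, g_i = partition.g_users, partition.g_items
    if g_u > n_u or g_i > n_i:
        raise ValueError(f"more non-empty groups ({g_u}, {g_i}) than nodes ({n_u}, {n_i})")
    return (
        lgamma(n_u + 1)
        - lgamma(n_u - g_u + 1)
        + lgamma(n_i + 1)
        - lgamma(n_i - g_i + 1)
    )


def corrected_hamiltonian(dataset: RatingDataset, partition: Partition) -> float:
    """H' = H + C, the quantity the labeled-group sampler targets."""
    return hamiltonian(count_blocks(dataset, partition)) + labeled_sampling_correction(partition)


# ---------------------------------------------------------------------------
# Incremental move evaluation


@dataclass(frozen=True)
class Move:
    """Single-node reassignment: move ``node`` on ``side`` to ``target`` label."""

    side: str  # "user" | "item"
    node: int
    target: int


def _block_term(row: np.ndarray, K: int) -> float:
    n = int(row.sum())
    if n == 0:
        return 0.0
    return lgamma(n + K) - sum(lgamma(int(x) + 1) for x in row) - lgamma(K)


def move_delta(
    dataset: RatingDataset,
    counts: BlockCountTable,
    partition: Partition,
    move: Move,
) -> float:
    """Change in the corrected Hamiltonian H' under a single-node move.

    Only the blocks incident to the node's old and new groups are touched;
    the result agrees with recomputing H' from scratch to ~1e-9.  A move to
    the node's current group yields exactly 0.  ``counts`` and ``partition``
    are left unmodified.
    """
    K = dataset.K
    if move.side == "user":
        assign, other = partition.user_assignment, partition.item_assignment
        n_side = dataset.n_users
        table = counts.counts  # indexed [own_group, other_group, r]
        own_axis = 0
    elif move.side == "item":
        assign, other = partition.item_assignment, partition.user_assignment
        n_side = dataset.n_items
        table = np.swapaxes(counts.counts, 0, 1)
        own_axis = 1
    else:
        raise ValueError(f"unknown side {move.side!r}")
    if not 0 <= move.node < n_side:
        raise ValueError(f"no {move.side} node {move.node}")
    if not 0 <= move.target < n_side:
        raise ValueError(f"target label {move.target} outside [0, {n_side})")
    a, b = int(assign[move.node]), int(move.target)
    if a == b:
        return 0.0

    # class counts of the node's own ratings, aggregated by the other side's group
    if move.side == "user":
        sel = dataset.users == move.node
        groups = other[dataset.items[sel]]
    else:
        sel = dataset.items == move.node
        groups = other[dataset.users[sel]]
    classes = dataset.ratings[sel] - 1
    delta = np.zeros((table.shape[1], K), dtype=np.int64)
    np.add.at(delta, (groups, classes), 1)
    touched = np.unique(groups)

    d_h = 0.0
    for beta in touched:
        old_a = table[a, beta]
        old_b = table[b, beta]
        d_h -= _block_term(old_a, K) + _block_term(old_b, K)
        d_h += _block_term(old_a - delta[beta], K) + _block_term(old_b + delta[beta], K)

    # correction term: only the non-empty group count can change
    sizes = np.bincount(assign, minlength=n_side)
    g = int((sizes > 0).sum())
    dg = (1 if sizes[b] == 0 else 0) - (1 if sizes[a] == 1 else 0)
    d_c = 0.0
    if dg == 1:
        d_c = np.log(n_side - g)
    elif dg == -1:
        d_c = -np.log(n_side - g + 1)
    return d_h + d_c


def apply_move(counts: BlockCountTable, partition: Partition, dataset: RatingDataset, move: Move) -> None:
    """Commit ``move`` to the partition and count table in place."""
    if move.side == "user":
        assign, other = partition.user_assignment, partition.item_assignment
        sel = dataset.users == move.node
        groups = other[dataset.items[sel]]
    else:
        assign, other = partition.item_assignment, partition.user_assignment
        sel = dataset.items == move.node
        groups = other[dataset.users[sel]]
    a, b = int(assign[move.node]), int(move.target)
    if a == b:
        return
    classes = dataset.ratings[sel] - 1
    if move.side == "user":
        np.add.at(counts.counts, (np.full(len(groups), a), groups, classes), -1)
        np.add.at(counts.counts, (np.full(len(groups), b), groups, classes), 1)
    else:
        np.add.at(counts.counts, (groups, np.full(len(groups), a), classes), -1)
        np.add.at(counts.counts, (groups, np.full(len(groups), b), classes), 1)
    assign[move.node] = b
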