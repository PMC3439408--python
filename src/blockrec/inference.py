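"""Metropolis sampling of the partition ensemble and Bayesian rating posteriors.

The posterior probability of an unobserved rating is an average over *all*
partitions of users and items into groups, each weighted by the marginal
likelihood exp(-H) of the block model it indexes:

    p(r_ui = r | R^O) = (1/Z) * sum_{P_U, P_I} exp(-H) * (n^r + 1) / (n + K)

where n^r and n are the class and total counts of the block containing the
query pair.  The sum is estimated with Metropolis sampling over labeled
assignments under the corrected Hamiltonian H' (see :mod:`blockrec.core`);
samples then carry the Boltzmann weight and the estimator is an unweighted
average.  ``exhaustive_posterior`` performs the exact summation on tiny
instances and is the oracle the sampler is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Hashable, Iterator, Literal, Sequence

import numpy as np

from .core import (
    Partition,
    RatingDataset,
    count_blocks,
    hamiltonian,
)
from . import _kernel

__all__ = [
    "SamplerConfig",
    "PartitionSample",
    "RatingPosterior",
    "run_chain",
    "run_ensemble",
    "posterior",
    "predict",
    "exhaustive_posterior",
]

PredictionRule = Literal["map", "mean", "median"]


@dataclass(frozen=True)
class SamplerConfig:
    """Settings for the multi-chain Metropolis sampler.

    One sweep attempts one move per node on average.  Chains are short,
    parallel and independent, started in different regions of the partition
    space; burn-in defaults to 20% of the sweeps and the sample interval to
    whatever yields ~100 samples per chain.
    """

    n_chains: int = 4
    sweeps_per_chain: int = 500
    burn_in_sweeps: int | None = None
    sample_interval_sweeps: int | None = None
    seed: int = 0
    init_groups: Literal["singletons", "one-group", "random-g"] = "random-g"

    def resolved(self) -> "SamplerConfig":
        burn = self.burn_in_sweeps
        if burn is None:
            burn = self.sweeps_per_chain // 5
        interval = self.sample_interval_sweeps
        if interval is None:
            interval = max(1, (self.sweeps_per_chain - burn) // 100)
        cfg = replace(self, burn_in_sweeps=burn, sample_interval_sweeps=interval)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.n_chains < 1 or self.sweeps_per_chain < 1:
            raise ValueError("n_chains and sweeps_per_chain must be >= 1")
        if self.burn_in_sweeps is not None and not (
            0 <= self.burn_in_sweeps < self.sweeps_per_chain
        ):
            raise ValueError("need 0 <= burn_in_sweeps < sweeps_per_chain")
        if self.sample_interval_sweeps is not None and self.sample_interval_sweeps < 1:
            raise ValueError("sample_interval_sweeps must be >= 1")
        if self.init_groups not in ("singletons", "one-group", "random-g"):
            raise ValueError(f"unknown init_groups strategy {self.init_groups!r}")


@dataclass
class PartitionSample:
    """Pooled (partition, H) pairs from all chains, with provenance."""

    user_samples: np.ndarray  # (S, n_users)
    item_samples: np.ndarray  # (S, n_items)
    h_values: np.ndarray  # (S,)
    chain_ids: np.ndarray  # (S,)
    sweep_indices: np.ndarray  # (S,)
    acceptance_rate: float = float("nan")

    def __len__(self) -> int:
        return len(self.h_values)

    def __iter__(self) -> Iterator[tuple[Partition, float]]:
        for s in range(len(self)):
            yield Partition(self.user_samples[s], self.item_samples[s]), float(self.h_values[s])

    @staticmethod
    def concatenate(parts: Sequence["PartitionSample"]) -> "PartitionSample":
        rates = [p.acceptance_rate for p in parts]
        return PartitionSample(
            np.concatenate([p.user_samples for p in parts]),
            np.concatenate([p.item_samples for p in parts]),
            np.concatenate([p.h_values for p in parts]),
            np.concatenate([p.chain_ids for p in parts]),
            np.concatenate([p.sweep_indices for p in parts]),
            float(np.mean(rates)),
        )


@dataclass
class RatingPosterior:
    """Per-query probability vectors over the K rating classes."""

    queries: list  # external (user id, item id) pairs
    probs: np.ndarray  # (n_queries, K)
    classes: np.ndarray = field(default=None)  # type: ignore[assignment]
    ordinal: bool = True

    def __post_init__(self) -> None:
        if self.classes is None:
            self.classes = np.arange(1, self.probs.shape[1] + 1)

    @property
    def K(self) -> int:
        return self.probs.shape[1]


def _chain_seed(seed: int, chain_index: int) -> int:
    """Deterministic sub-seed: one SeedSequence spawn per chain, kept < 2^31."""
    child = np.random.SeedSequence(seed).spawn(chain_index + 1)[chain_index]
    return int(child.generate_state(1)[0] & 0x7FFFFFFF)


def _initial_partition(n: int, strategy: str, rng: np.random.Generator) -> np.ndarray:
    if strategy == "singletons":
        return np.arange(n, dtype=np.int64)
    if strategy == "one-group":
        return np.zeros(n, dtype=np.int64)
    g = int(rng.integers(1, n + 1))
    return rng.integers(0, g, size=n).astype(np.int64)


def run_chain(
    dataset: RatingDataset,
    config: SamplerConfig,
    chain_index: int = 0,
) -> PartitionSample:
    """Run a single Metropolis chain and return its thinned sub-sample.

    The chain's stationary distribution over labeled assignments is
    proportional to exp(-H'); the recorded H values are the *uncorrected*
    Hamiltonian, recomputed exactly at emission time.
    """
    if dataset.n_users < 1 or dataset.n_items < 1:
        raise ValueError("dataset must have at least one user and one item")
    cfg = config.resolved()
    seed = _chain_seed(cfg.seed, chain_index)
    rng = np.random.default_rng(seed)
    sigma = _initial_partition(dataset.n_users, cfg.init_groups, rng)
    tau = _initial_partition(dataset.n_items, cfg.init_groups, rng)

    table = count_blocks(dataset, Partition(sigma, tau))
    counts = np.ascontiguousarray(table.counts)
    totals = np.ascontiguousarray(table.totals)
    u_ptr, u_items, u_ratings, i_ptr, i_users, i_ratings = dataset.adjacency()
    lg = _kernel.lgamma_table(dataset.n_observed, dataset.K)

    out_sigma, out_tau, out_h, out_sweep, rate = _kernel.run_sweeps(
        sigma, tau, counts, totals,
        u_ptr, u_items, u_ratings,
        i_ptr, i_users, i_ratings,
        dataset.K, cfg.sweeps_per_chain, cfg.burn_in_sweeps, cfg.sample_interval_sweeps,
        int(rng.integers(0, 2**31 - 1)),
        lg,
    )
    return PartitionSample(
        out_sigma, out_tau, out_h,
        np.full(len(out_h), chain_index, dtype=np.int64),
        out_sweep,
        float(rate),
    )


def run_ensemble(dataset: RatingDataset, config: SamplerConfig) -> PartitionSample:
    """Pool samples from ``config.n_chains`` independent chains.

    Sub-seeds are derived deterministically from ``config.seed``, and each
    chain starts from its own region of the partition space per the
    ``init_groups`` strategy.
    """
    cfg = config.resolved()
    return PartitionSample.concatenate(
        [run_chain(dataset, cfg, c) for c in range(cfg.n_chains)]
    )


def _resolve_queries(dataset: RatingDataset, queries: Sequence) -> tuple[list, np.ndarray, np.ndarray]:
    qu = np.empty(len(queries), dtype=np.int64)
    qi = np.empty(len(queries), dtype=np.int64)
    ext = []
    for k, (uid, iid) in enumerate(queries):
        qu[k] = dataset.user_of(uid)
        qi[k] = dataset.item_of(iid)
        ext.append((uid, iid))
    return ext, qu, qi


def posterior(
    dataset: RatingDataset,
    sample: PartitionSample,
    queries: Sequence[tuple[Hashable, Hashable]],
) -> RatingPosterior:
    """Monte-Carlo rating posterior from a partition sample.

    For each sampled partition the query pair's block contributes the
    Dirichlet-multinomial predictive (n^r + 1)/(n + K) — the Laplace rule of
    succession; the posterior is the unweighted average over samples (the
    sample frequencies already carry the Boltzmann weight).
    """
    if len(sample) == 0:
        raise ValueError("empty partition sample")
    ext, qu, qi = _resolve_queries(dataset, queries)
    K = dataset.K
    acc = np.zeros((len(queries), K), dtype=np.float64)
    r0 = dataset.ratings - 1
    for s in range(len(sample)):
        sigma = sample.user_samples[s]
        tau = sample.item_samples[s]
        counts = np.zeros((dataset.n_users, dataset.n_items, K), dtype=np.int64)
        if dataset.n_observed:
            np.add.at(counts, (sigma[dataset.users], tau[dataset.items], r0), 1)
        block = counts[sigma[qu], tau[qi]]  # (n_queries, K)
        acc += (block + 1) / (block.sum(axis=1, keepdims=True) + K)
    return RatingPosterior(ext, acc / len(sample))


def predict(posterior_: RatingPosterior, rule: PredictionRule = "map") -> np.ndarray:
    """Point predictions from posterior vectors.

    map: most probable class (ties -> lowest class); mean: real-valued
    expectation sum_r r * p(r); median: smallest class with cumulative
    probability >= 1/2.  mean/median require ordinal classes.
    """
    p = posterior_.probs
    classes = np.asarray(posterior_.classes, dtype=float)
    if rule == "map":
        return np.asarray(posterior_.classes)[np.argmax(p, axis=1)]
    if not posterior_.ordinal:
        raise ValueError(f"rule {rule!r} requires ordinal rating classes")
    if rule == "mean":
        return p @ classes
    if rule == "median":
        cum = np.cumsum(p, axis=1)
        idx = np.argmax(cum >= 0.5 - 1e-12, axis=1)
        return np.asarray(posterior_.classes)[idx]
    raise ValueError(f"unknown prediction rule {rule!r}")


def _set_partitions(n: int) -> list[np.ndarray]:
    """All set partitions of n elements as label arrays (Bell(n) of them)."""
    from sympy.utilities.iterables import multiset_partitions

    if n == 0:
        return [np.zeros(0, dtype=np.int64)]
    out = []
    for blocks in multiset_partitions(list(range(n))):
        labels = np.empty(n, dtype=np.int64)
        for g, block in enumerate(blocks):
            for node in block:
                labels[node] = g
        out.append(labels)
    return out


def _bell(n: int) -> int:
    from sympy import bell

    return int(bell(n))


def exhaustive_posterior(
    dataset: RatingDataset,
    queries: Sequence[tuple[Hashable, Hashable]],
    max_pairs: int = 10**6,
) -> RatingPosterior:
    """Exact posterior by summation over all unlabeled partition pairs.

    Feasible only when Bell(n_users) * Bell(n_items) <= ``max_pairs``; used
    as the ground-truth oracle for the Metropolis estimator.
    """
    n_pairs = _bell(dataset.n_users) * _bell(dataset.n_items)
    if n_pairs > max_pairs:
        raise ValueError(
            f"exhaustive enumeration needs {n_pairs} partition pairs, cap is {max_pairs}"
        )
    ext, qu, qi = _resolve_queries(dataset, queries)
    K = dataset.K
    user_parts = _set_partitions(dataset.n_users)
    item_parts = _set_partitions(dataset.n_items)

    h_vals = np.empty(len(user_parts) * len(item_parts))
    preds = np.empty((len(h_vals), len(queries), K))
    k = 0
    for sigma in user_parts:
        for tau in item_parts:
            part = Partition(sigma, tau)
            table = count_blocks(dataset, part)
            h_vals[k] = hamiltonian(table)
            block = table.counts[sigma[qu], tau[qi]]
            preds[k] = (block + 1) / (block.sum(axis=1, keepdims=True) + K)
            k += 1
    w = np.exp(-(h_vals - h_vals.min()))
    w /= w.sum()
    return RatingPosterior(ext, np.einsum("s,sqk->qk", w, preds))
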