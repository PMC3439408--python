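"""Metrics, benchmark protocols, co-classification and attribute analysis.

``benchmark_model`` runs the synthetic like/dislike protocol over a grid of
the interpolation parameter lambda and compares algorithms against the
Bayes-optimal ceiling; ``benchmark_real`` scores algorithms on supplied
train/test splits (e.g. the five 80k/20k MovieLens splits) by exact-match
accuracy and mean absolute error.  ``coclassification`` turns a partition
sample into the probability that two nodes share a group, the basis for
consensus grouping and for correlating sampled structure with node
attributes (gender, age, genre overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import (
    discretize,
    item_sim_fit,
    itemitem_predict,
    naive_predict,
    svd_fit,
    svd_predict,
)
from .core import RatingDataset
from .inference import PartitionSample, SamplerConfig, posterior, predict, run_ensemble
from .synthetic import GeneratorConfig, generate, optimal_accuracy

__all__ = [
    "accuracy",
    "mae",
    "relative_improvement",
    "benchmark_model",
    "benchmark_real",
    "CoClassificationMatrix",
    "coclassification",
    "consensus_partition",
    "attribute_vs_coclass",
    "genre_overlap",
]


def accuracy(predicted: Sequence, true: Sequence) -> float:
    """Fraction of exactly matching class predictions."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {true.shape}")
    if predicted.size == 0:
        raise ValueError("empty prediction vector")
    return float(np.mean(predicted == true))


def mae(predicted: Sequence, true: Sequence) -> float:
    """Mean absolute deviation of predictions from true ratings."""
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.shape != true.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {true.shape}")
    if predicted.size == 0:
        raise ValueError("empty prediction vector")
    return float(np.mean(np.abs(predicted - true)))


def relative_improvement(a: float, b: float, baseline: float) -> float:
    """Improvement of A over B relative to B's improvement over the baseline."""
    gain_b = b - baseline
    if gain_b == 0:
        raise ValueError("reference improvement is zero")
    return (a - b) / gain_b


def relative_improvement_table(
    results: pd.DataFrame,
    metric: str = "accuracy",
    baseline: str = "naive",
) -> pd.DataFrame:
    """Pairwise relative improvements from a benchmark result table.

    For every split and every ordered pair (A, B) of non-baseline
    algorithms, reports (A - B)/(B - baseline) on the chosen metric — the
    gain of A over B expressed as a fraction of B's own gain over the
    baseline recommender.  For error metrics (MAE) the signs are flipped so
    that positive still means A improves on B.
    """
    lower_is_better = metric.startswith("mae")
    sign = -1.0 if lower_is_better else 1.0
    rows = []
    for split, grp in results.groupby("split"):
        scores = grp.set_index("algorithm")[metric]
        if baseline not in scores.index:
            raise ValueError(f"baseline algorithm {baseline!r} missing from split {split}")
        for a in scores.index:
            for b in scores.index:
                if baseline in (a, b) or a == b:
                    continue
                gain_b = sign * (scores[b] - scores[baseline])
                if gain_b == 0:
                    continue
                rows.append(
                    {
                        "split": split,
                        "algorithm": a,
                        "reference": b,
                        "metric": metric,
                        "relative_improvement": sign * (scores[a] - scores[b]) / gain_b,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Benchmark protocols


def _score_algorithm(
    algorithm: str,
    train: RatingDataset,
    queries: list,
    truths: np.ndarray,
    sampler: SamplerConfig,
    svd_params: dict,
    itemitem_k: int,
) -> dict:
    """Fit one algorithm and score accuracy (and MAE where ordinal)."""
    K = train.K
    row: dict = {"algorithm": algorithm}
    if algorithm == "sbm":
        sample = run_ensemble(train, sampler)
        post = posterior(train, sample, queries)
        cls = predict(post, "map")
        row["accuracy"] = accuracy(cls, truths)
        row["mae"] = mae(cls, truths)
    elif algorithm == "naive":
        raw = naive_predict(train, queries)
        row["accuracy"] = accuracy(discretize(raw, K), truths)
        row["mae"] = mae(raw, truths)
    elif algorithm == "svd":
        model = svd_fit(train, **svd_params)
        raw = svd_predict(model, queries)
        row["accuracy"] = accuracy(discretize(raw, K), truths)
        row["mae"] = mae(raw, truths)
        row["mae_discretized"] = mae(discretize(raw, K), truths)
    elif algorithm == "itemitem":
        model = item_sim_fit(train, k=itemitem_k)
        raw = itemitem_predict(train, model, queries)
        row["accuracy"] = accuracy(discretize(raw, K), truths)
        row["mae"] = mae(raw, truths)
        row["mae_discretized"] = mae(discretize(raw, K), truths)
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return row


def benchmark_model(
    lambdas: Sequence[float],
    template: GeneratorConfig,
    algorithms: Sequence[str] = ("sbm", "naive"),
    replicates: int = 5,
    seed: int = 0,
    sampler: SamplerConfig | None = None,
    svd_params: dict | None = None,
    itemitem_k: int = 30,
) -> pd.DataFrame:
    """Synthetic-ratings benchmark over a lambda grid.

    For each lambda and replicate a fresh realization is generated from
    ``template`` (with a replicate-specific seed derived from ``seed``),
    each algorithm is fit on the training ratings and scored on the test
    pairs, and the optimal accuracy is recorded alongside.  Returns a tidy
    table with one row per (lambda, replicate, algorithm).
    """
    sampler = sampler or SamplerConfig()
    svd_params = svd_params or {}
    rows = []
    ss = np.random.SeedSequence(seed)
    for lam in lambdas:
        for rep in range(replicates):
            rep_seed = int(ss.spawn(1)[0].generate_state(1)[0] & 0x7FFFFFFF)
            cfg = replace(template, lam=float(lam), seed=rep_seed)
            train, test, truth = generate(cfg)
            queries = [(u, i) for u, i, _ in test]
            truths = np.array([r for _, _, r in test])
            expected_opt, realized_opt = optimal_accuracy(truth, test)
            for algorithm in algorithms:
                row = _score_algorithm(
                    algorithm, train, queries, truths,
                    replace(sampler, seed=rep_seed), svd_params, itemitem_k,
                )
                row.update(
                    {
                        "lambda": float(lam),
                        "replicate": rep,
                        "seed": rep_seed,
                        "n_train": cfg.n_observed,
                        "n_test": cfg.n_test,
                        "optimal_accuracy": expected_opt,
                        "optimal_accuracy_realized": realized_opt,
                    }
                )
                rows.append(row)
    return pd.DataFrame(rows)


def benchmark_real(
    splits: Sequence[tuple[RatingDataset, Sequence[tuple]]],
    algorithms: Sequence[str] = ("sbm", "naive", "svd", "itemitem"),
    sampler: SamplerConfig | None = None,
    svd_params: dict | None = None,
    itemitem_k: int = 30,
) -> pd.DataFrame:
    """Score algorithms on pre-made train/test splits (accuracy and MAE).

    Each split is ``(train_dataset, test_triples)`` with disjoint train and
    test pairs.  When the row set allows it, relative-improvement ratios of
    each algorithm over the next-best non-naive one are best computed from
    the returned table with :func:`relative_improvement`.
    """
    sampler = sampler or SamplerConfig()
    svd_params = svd_params or {}
    rows = []
    for split_id, (train, test) in enumerate(splits):
        observed = set(zip(train.users.tolist(), train.items.tolist()))
        for uid, iid, _ in test:
            u = train.user_of(uid)
            i = train.item_of(iid)
            if (u, i) in observed:
                raise ValueError(f"test pair ({uid!r}, {iid!r}) also present in training split")
        queries = [(u, i) for u, i, _ in test]
        truths = np.array([r for _, _, r in test])
        for algorithm in algorithms:
            row = _score_algorithm(
                algorithm, train, queries, truths,
                replace(sampler, seed=sampler.seed + split_id),
                svd_params, itemitem_k,
            )
            row.update({"split": split_id, "n_train": train.n_observed, "n_test": len(test)})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Co-classification and attribute correlation


@dataclass
class CoClassificationMatrix:
    """Pairwise same-group frequency across sampled partitions."""

    matrix: np.ndarray  # (n, n), symmetric, unit diagonal
    side: str

    def validate(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T):
            raise ValueError("co-classification matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("diagonal must be 1")
        if (m < -1e-12).any() or (m > 1 + 1e-12).any():
            raise ValueError("entries must lie in [0, 1]")


def coclassification(sample: PartitionSample, side: str = "users") -> CoClassificationMatrix:
    """Probability that two nodes of one side share a group in the ensemble."""
    if len(sample) == 0:
        raise ValueError("empty partition sample")
    if side == "users":
        assignments = sample.user_samples
    elif side == "items":
        assignments = sample.item_samples
    else:
        raise ValueError(f"side must be 'users' or 'items', got {side!r}")
    n = assignments.shape[1]
    acc = np.zeros((n, n))
    for s in range(assignments.shape[0]):
        a = assignments[s]
        acc += a[:, None] == a[None, :]
    return CoClassificationMatrix(acc / assignments.shape[0], side)


def consensus_partition(coclass: CoClassificationMatrix, threshold: float = 0.5) -> np.ndarray:
    """Consensus grouping by average-linkage clustering of 1 - coclass.

    The dendrogram is cut at distance ``1 - threshold``, so nodes whose
    average co-classification frequency exceeds ``threshold`` end up
    together.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    m = np.clip(coclass.matrix, 0.0, 1.0)
    n = m.shape[0]
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    dist = squareform(1.0 - m, checks=False)
    z = linkage(dist, method="average")
    return fcluster(z, t=1.0 - threshold, criterion="distance").astype(np.int64)


def attribute_vs_coclass(
    coclass: CoClassificationMatrix,
    attributes: Sequence,
    n_bins: int = 10,
    kind: str = "categorical",
    min_pairs_flag: int = 20,
) -> pd.DataFrame:
    """Bin node pairs by co-classification frequency and summarize attributes.

    For categorical attributes each bin reports the fraction of same-valued
    pairs; for numeric attributes the mean absolute difference.  Pairs with
    a missing attribute (None/NaN) are excluded and counted.  Bins with
    fewer than ``min_pairs_flag`` pairs are flagged as unreliable.
    """
    if n_bins < 1:
        raise ValueError("need at least one bin")
    m = coclass.matrix
    n = m.shape[0]
    if len(attributes) != n:
        raise ValueError(f"{len(attributes)} attributes for {n} nodes")
    attrs = list(attributes)
    valid = np.array(
        [a is not None and not (isinstance(a, float) and np.isnan(a)) for a in attrs]
    )
    iu, ju = np.triu_indices(n, k=1)
    ok = valid[iu] & valid[ju]
    n_excluded = int((~ok).sum())
    iu, ju = iu[ok], ju[ok]
    freq = m[iu, ju]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(freq, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        count = int(sel.sum())
        row = {
            "bin_low": edges[b],
            "bin_high": edges[b + 1],
            "n_pairs": count,
            "n_pairs_excluded": n_excluded,
            "flagged": count < min_pairs_flag,
        }
        if count:
            if kind == "categorical":
                same = [attrs[i] == attrs[j] for i, j in zip(iu[sel], ju[sel])]
                row["same_fraction"] = float(np.mean(same))
            elif kind == "numeric":
                diffs = [abs(float(attrs[i]) - float(attrs[j])) for i, j in zip(iu[sel], ju[sel])]
                row["mean_abs_difference"] = float(np.mean(diffs))
            else:
                raise ValueError(f"kind must be 'categorical' or 'numeric', got {kind!r}")
        rows.append(row)
    return pd.DataFrame(rows)


def genre_overlap(genres_i: set, genres_j: set) -> float:
    """Jaccard index of two genre sets (undefined for an empty set)."""
    if not genres_i or not genres_j:
        raise ValueError("genre overlap is undefined for an empty genre set")
    gi, gj = set(genres_i), set(genres_j)
    return len(gi & gj) / len(gi | gj)
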