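"""Collaborative-filtering baselines: naive item mean, Funk-SVD, item-item kNN.

These are the standard recommenders the block-model approach is compared
against.  The naive recommender predicts each item's mean observed rating.
The matrix-factorization baseline (Funk-SVD) models

    r_hat(u, i) = mu + b_u + b_i + p_u . q_i

and minimizes the regularized squared error over observed ratings by
stochastic gradient descent.  The item-item recommender averages the user's
own ratings of the k items most similar to the target, with similarity the
adjusted cosine (user means removed) over co-rating users.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RatingDataset

__all__ = [
    "SVDModel",
    "ItemSimilarityModel",
    "naive_predict",
    "svd_fit",
    "svd_predict",
    "item_sim_fit",
    "itemitem_predict",
    "discretize",
]


def _item_means(train: RatingDataset) -> tuple[np.ndarray, float]:
    """Per-item mean rating and the global fallback mean."""
    sums = np.zeros(train.n_items)
    counts = np.zeros(train.n_items)
    np.add.at(sums, train.items, train.ratings)
    np.add.at(counts, train.items, 1)
    global_mean = float(train.ratings.mean()) if train.n_observed else (1 + train.K) / 2
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), global_mean)
    return means, global_mean


def naive_predict(train: RatingDataset, queries) -> np.ndarray:
    """Predict each item's average observed rating.

    Items with no training ratings fall back to the global training mean.
    """
    means, _ = _item_means(train)
    return np.array([means[train.item_of(iid)] for _, iid in queries])


# ---------------------------------------------------------------------------
# Funk-SVD with bias terms


@dataclass
class SVDModel:
    mu: float
    b_user: np.ndarray
    b_item: np.ndarray
    p: np.ndarray  # (n_users, f)
    q: np.ndarray  # (n_items, f)
    f: int
    rate: float
    reg: float
    epochs: int
    seed: int
    user_index: dict
    item_index: dict

    def objective(self, train: RatingDataset) -> float:
        """Regularized squared-error objective on the training set."""
        pred = (
            self.mu
            + self.b_user[train.users]
            + self.b_item[train.items]
            + np.einsum("uf,uf->u", self.p[train.users], self.q[train.items])
        )
        err = float(np.sum((train.ratings - pred) ** 2))
        penalty = self.reg * (
            np.sum(self.p[train.users] ** 2)
            + np.sum(self.q[train.items] ** 2)
            + np.sum(self.b_user[train.users] ** 2)
            + np.sum(self.b_item[train.items] ** 2)
        )
        return err + float(penalty)


def svd_fit(
    train: RatingDataset,
    f: int = 40,
    rate: float = 0.002,
    reg: float = 0.02,
    epochs: int = 100,
    seed: int = 0,
) -> SVDModel:
    """Fit biases and latent factors by per-observation gradient steps.

    Biases start at zero, factors at N(0, 0.01); observations are shuffled
    once per epoch with the seeded generator.  ``epochs=0`` returns the
    initialized model untouched.
    """
    if train.n_observed == 0:
        raise ValueError("cannot fit SVD on an empty training set")
    if f < 1:
        raise ValueError("need at least one latent factor")
    if rate <= 0 or reg < 0:
        raise ValueError("learning rate must be positive and regularization non-negative")
    rng = np.random.default_rng(seed)
    mu = float(train.ratings.mean())
    b_u = np.zeros(train.n_users)
    b_i = np.zeros(train.n_items)
    p = rng.normal(0.0, 0.1, size=(train.n_users, f))
    q = rng.normal(0.0, 0.1, size=(train.n_items, f))

    users, items = train.users, train.items
    ratings = train.ratings.astype(float)
    for _ in range(epochs):
        order = rng.permutation(train.n_observed)
        for k in order:
            u, i = users[k], items[k]
            err = ratings[k] - (mu + b_u[u] + b_i[i] + p[u] @ q[i])
            b_u[u] += rate * (err - reg * b_u[u])
            b_i[i] += rate * (err - reg * b_i[i])
            pu = p[u].copy()
            p[u] += rate * (err * q[i] - reg * pu)
            q[i] += rate * (err * pu - reg * q[i])
    return SVDModel(
        mu, b_u, b_i, p, q, f, rate, reg, epochs, seed,
        train.user_index, train.item_index,
    )


def discretize(raw: np.ndarray, K: int) -> np.ndarray:
    """Round real-valued predictions to the nearest class, clipped to 1..K.

    Halfway ties break toward the lower class.
    """
    return np.clip(np.ceil(np.asarray(raw) - 0.5), 1, K).astype(int)


def svd_predict(model: SVDModel, queries, discretize_to: int | None = None) -> np.ndarray:
    """r_hat = mu + b_u + b_i + p_u . q_i per query.

    Users or items unseen during training use zero bias and zero factors.
    Raw predictions may fall outside the rating range; only the discretized
    path (``discretize_to=K``) rounds and clips.
    """
    out = np.empty(len(queries))
    for k, (uid, iid) in enumerate(queries):
        pred = model.mu
        u = model.user_index.get(uid)
        i = model.item_index.get(iid)
        if u is not None:
            pred += model.b_user[u]
        if i is not None:
            pred += model.b_item[i]
        if u is not None and i is not None:
            pred += float(model.p[u] @ model.q[i])
        out[k] = pred
    if discretize_to is not None:
        return discretize(out, discretize_to)
    return out


# ---------------------------------------------------------------------------
# Item-item kNN with adjusted cosine similarity


@dataclass
class ItemSimilarityModel:
    similarity: np.ndarray  # (n_items, n_items), symmetric, zero diagonal
    k: int


def item_sim_fit(train: RatingDataset, k: int = 30) -> ItemSimilarityModel:
    """Adjusted-cosine similarity between all item pairs.

    Each user's mean rating is subtracted first; the cosine is taken over
    the users who rated both items.  Pairs with no co-rating users (or a
    zero adjusted norm on the co-rated support) get similarity 0.
    """
    n_u, n_i = train.n_users, train.n_items
    x = np.zeros((n_u, n_i))  # adjusted ratings
    m = np.zeros((n_u, n_i))  # observation mask
    user_sum = np.zeros(n_u)
    user_cnt = np.zeros(n_u)
    np.add.at(user_sum, train.users, train.ratings)
    np.add.at(user_cnt, train.users, 1)
    user_mean = np.divide(user_sum, np.maximum(user_cnt, 1))
    x[train.users, train.items] = train.ratings - user_mean[train.users]
    m[train.users, train.items] = 1.0

    num = x.T @ x  # co-rated numerators
    sq = x**2
    # norm of item i restricted to users who also rated j
    pairnorm = sq.T @ m  # pairnorm[i, j] = sum_{u rated j} x_ui^2
    denom = np.sqrt(pairnorm * pairnorm.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(sim, 0.0)
    return ItemSimilarityModel(sim, k)


def itemitem_predict(
    train: RatingDataset,
    model: ItemSimilarityModel,
    queries,
    k: int | None = None,
) -> np.ndarray:
    """Similarity-weighted average of the k nearest rated neighbors.

    Among the items the query user has rated, the k most similar to the
    target with strictly positive similarity contribute sim-weighted
    ratings; with no usable neighbor the naive item mean is used.
    """
    k = model.k if k is None else k
    naive = naive_predict(train, queries)
    rated_by: dict[int, list[tuple[int, float]]] = {}
    for u, i, r in zip(train.users, train.items, train.ratings):
        rated_by.setdefault(int(u), []).append((int(i), float(r)))
    out = np.empty(len(queries))
    for idx, (uid, iid) in enumerate(queries):
        u = train.user_of(uid)
        i = train.item_of(iid)
        rated = rated_by.get(u, [])
        cands = [(model.similarity[i, j], r) for j, r in rated if j != i]
        cands = [(s, r) for s, r in cands if s > 0]
        cands.sort(key=lambda t: -t[0])
        cands = cands[:k]
        wsum = sum(s for s, _ in cands)
        if wsum > 0:
            out[idx] = sum(s * r for s, r in cands) / wsum
        else:
            out[idx] = naive[idx]
    return out
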