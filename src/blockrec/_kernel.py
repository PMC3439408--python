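"""Compiled inner loop of the Metropolis partition sampler.

The kernel maintains the dense block-count table and the running corrected
Hamiltonian H' = H + C, proposes single-node relabelings, and accepts with
probability min(1, exp(-dH')).  Log-gamma values are looked up in a
precomputed table (arguments are integer counts bounded by the number of
observed ratings), which keeps a move evaluation at a few hundred
nanoseconds.  Recorded H values are recomputed from the count table at
emission time so they are exact, not accumulated deltas.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_sweeps", "lgamma_table"]


def lgamma_table(dataset_size: int, K: int) -> np.ndarray:
    """lnGamma(i) for integer i up to dataset_size + K + 2."""
    from scipy.special import gammaln

    n = dataset_size + K + 3
    table = np.zeros(n, dtype=np.float64)
    table[1:] = gammaln(np.arange(1, n, dtype=np.float64))
    return table


@njit(cache=True)
def _block_term(counts, totals, a, b, K, lg):
    n = totals[a, b]
    if n == 0:
        return 0.0
    s = lg[n + K] - lg[K]
    for r in range(K):
        s -= lg[counts[a, b, r] + 1]
    return s


@njit(cache=True)
def _hamiltonian_from_counts(counts, totals, K, lg):
    h = 0.0
    for a in range(counts.shape[0]):
        for b in range(counts.shape[1]):
            h += _block_term(counts, totals, a, b, K, lg)
    return h


@njit(cache=True)
def _attempt_move(
    assign, other_assign, sizes, g, n_side,
    ptr, adj_other, adj_rating, node,
    target, counts, totals, own_is_user, K, lg,
    scratch, scratch_tot, touched,
):
    """Evaluate and possibly commit one single-node relabeling.

    Returns (accepted, new_g, dlog).  ``scratch``/``scratch_tot`` are
    zeroed work arrays indexed by the *other* side's group label;
    ``touched`` is a work list of the labels this node's ratings reach.
    """
    a = assign[node]
    if target == a:
        return True, g, 0.0

    n_touch = 0
    for idx in range(ptr[node], ptr[node + 1]):
        beta = other_assign[adj_other[idx]]
        if scratch_tot[beta] == 0:
            touched[n_touch] = beta
            n_touch += 1
        scratch[beta, adj_rating[idx]] += 1
        scratch_tot[beta] += 1

    d_h = 0.0
    for t in range(n_touch):
        beta = touched[t]
        m = scratch_tot[beta]
        if own_is_user:
            na, nb = totals[a, beta], totals[target, beta]
            # old terms
            d_h -= _block_term(counts, totals, a, beta, K, lg)
            d_h -= _block_term(counts, totals, target, beta, K, lg)
            # new terms
            if na - m > 0:
                s = lg[na - m + K] - lg[K]
                for r in range(K):
                    s -= lg[counts[a, beta, r] - scratch[beta, r] + 1]
                d_h += s
            s = lg[nb + m + K] - lg[K]
            for r in range(K):
                s -= lg[counts[target, beta, r] + scratch[beta, r] + 1]
            d_h += s
        else:
            na, nb = totals[beta, a], totals[beta, target]
            d_h -= _block_term(counts, totals, beta, a, K, lg)
            d_h -= _block_term(counts, totals, beta, target, K, lg)
            if na - m > 0:
                s = lg[na - m + K] - lg[K]
                for r in range(K):
                    s -= lg[counts[beta, a, r] - scratch[beta, r] + 1]
                d_h += s
            s = lg[nb + m + K] - lg[K]
            for r in range(K):
                s -= lg[counts[beta, target, r] + scratch[beta, r] + 1]
            d_h += s

    dg = 0
    if sizes[a] == 1:
        dg -= 1
    if sizes[target] == 0:
        dg += 1
    d_c = 0.0
    if dg == 1:
        d_c = np.log(n_side - g)
    elif dg == -1:
        d_c = -np.log(n_side - g + 1)

    dlog = d_h + d_c
    accept = dlog <= 0.0 or np.random.random() < np.exp(-dlog)
    if accept:
        for t in range(n_touch):
            beta = touched[t]
            m = scratch_tot[beta]
            if own_is_user:
                for r in range(K):
                    counts[a, beta, r] -= scratch[beta, r]
                    counts[target, beta, r] += scratch[beta, r]
                totals[a, beta] -= m
                totals[target, beta] += m
            else:
                for r in range(K):
                    counts[beta, a, r] -= scratch[beta, r]
                    counts[beta, target, r] += scratch[beta, r]
                totals[beta, a] -= m
                totals[beta, target] += m
        assign[node] = target
        sizes[a] -= 1
        sizes[target] += 1
        g += dg

    for t in range(n_touch):  # clear scratch
        beta = touched[t]
        for r in range(K):
            scratch[beta, r] = 0
        scratch_tot[beta] = 0
    return accept, g, dlog


@njit(cache=True)
def run_sweeps(
    sigma, tau,
    counts, totals,
    u_ptr, u_items, u_ratings,
    i_ptr, i_users, i_ratings,
    K, n_sweeps, burn_in, interval,
    seed,
    lg,
):
    """Run ``n_sweeps`` sweeps, mutating the partition state in place.

    One sweep attempts ``n_users + n_items`` moves, each picking a node
    uniformly at random on either side and a uniformly random target label
    among that side's labels.  After ``burn_in`` sweeps one sample is
    emitted every ``interval`` sweeps.  Returns stacked user assignments,
    item assignments, exact H values, sweep indices, and the overall
    acceptance rate.
    """
    np.random.seed(seed)
    n_u = sigma.shape[0]
    n_i = tau.shape[0]
    usize = np.zeros(n_u, dtype=np.int64)
    isize = np.zeros(n_i, dtype=np.int64)
    for u in range(n_u):
        usize[sigma[u]] += 1
    for i in range(n_i):
        isize[tau[i]] += 1
    g_u = int((usize > 0).sum())
    g_i = int((isize > 0).sum())

    scratch_i = np.zeros((n_i, K), dtype=np.int64)
    scratch_tot_i = np.zeros(n_i, dtype=np.int64)
    touched_i = np.zeros(n_i, dtype=np.int64)
    scratch_u = np.zeros((n_u, K), dtype=np.int64)
    scratch_tot_u = np.zeros(n_u, dtype=np.int64)
    touched_u = np.zeros(n_u, dtype=np.int64)

    n_samples = 0
    if n_sweeps > burn_in:
        n_samples = (n_sweeps - burn_in + interval - 1) // interval
    out_sigma = np.empty((n_samples, n_u), dtype=np.int64)
    out_tau = np.empty((n_samples, n_i), dtype=np.int64)
    out_h = np.empty(n_samples, dtype=np.float64)
    out_sweep = np.empty(n_samples, dtype=np.int64)

    total_nodes = n_u + n_i
    accepted = 0
    attempted = 0
    k = 0
    for sweep in range(n_sweeps):
        for _ in range(total_nodes):
            node = np.random.randint(0, total_nodes)
            if node < n_u:
                target = np.random.randint(0, n_u)
                ok, g_u, _ = _attempt_move(
                    sigma, tau, usize, g_u, n_u,
                    u_ptr, u_items, u_ratings, node,
                    target, counts, totals, True, K, lg,
                    scratch_i, scratch_tot_i, touched_i,
                )
            else:
                target = np.random.randint(0, n_i)
                ok, g_i, _ = _attempt_move(
                    tau, sigma, isize, g_i, n_i,
                    i_ptr, i_users, i_ratings, node - n_u,
                    target, counts, totals, False, K, lg,
                    scratch_u, scratch_tot_u, touched_u,
                )
            attempted += 1
            if ok:
                accepted += 1
        if sweep >= burn_in and (sweep - burn_in) % interval == 0:
            out_sigma[k] = sigma
            out_tau[k] = tau
            out_h[k] = _hamiltonian_from_counts(counts, totals, K, lg)
            out_sweep[k] = sweep
            k += 1

    return out_sigma[:k], out_tau[:k], out_h[:k], out_sweep[:k], accepted / max(attempted, 1)
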