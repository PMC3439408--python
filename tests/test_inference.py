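"""Metropolis sampler, posterior estimator, predictions, exhaustive oracle."""

import numpy as np
import pytest

import blockrec as br
from blockrec.core import canonical_labels
from blockrec.inference import _bell, _set_partitions


class TestSamplerConfig:
    def test_defaults_resolve(self):
        cfg = br.SamplerConfig(sweeps_per_chain=1000).resolved()
        assert cfg.burn_in_sweeps == 200
        assert cfg.sample_interval_sweeps == 8  # ~100 samples per chain

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            br.SamplerConfig(sweeps_per_chain=10, burn_in_sweeps=10).resolved()
        with pytest.raises(ValueError):
            br.SamplerConfig(n_chains=0).resolved()
        with pytest.raises(ValueError):
            br.SamplerConfig(init_groups="nope").resolved()


class TestRunChain:
    def test_single_pair_dataset_constant(self):
        ds = br.make_fixture("single").dataset
        s = br.run_chain(ds, br.SamplerConfig(sweeps_per_chain=50, seed=0))
        # Bell(1) = 1: the only partition pair, H constant across samples
        assert len(s) > 0
        assert np.all(s.user_samples == 0) and np.all(s.item_samples == 0)
        assert np.allclose(s.h_values, s.h_values[0])

    def test_recorded_h_matches_recomputation(self, random_dataset):
        s = br.run_chain(random_dataset, br.SamplerConfig(sweeps_per_chain=200, seed=1))
        for k in range(0, len(s), 7):
            part = br.Partition(s.user_samples[k], s.item_samples[k])
            h = br.hamiltonian(br.count_blocks(random_dataset, part))
            assert s.h_values[k] == pytest.approx(h, abs=1e-9)

    def test_deterministic_given_seed(self, random_dataset):
        cfg = br.SamplerConfig(n_chains=1, sweeps_per_chain=100, seed=9)
        a = br.run_chain(random_dataset, cfg, 0)
        b = br.run_chain(random_dataset, cfg, 0)
        assert np.array_equal(a.user_samples, b.user_samples)
        assert np.array_equal(a.item_samples, b.item_samples)
        assert np.array_equal(a.h_values, b.h_values)

    def test_chains_differ_across_indices(self, random_dataset):
        cfg = br.SamplerConfig(n_chains=2, sweeps_per_chain=100, seed=9)
        a = br.run_chain(random_dataset, cfg, 0)
        b = br.run_chain(random_dataset, cfg, 1)
        assert not (
            np.array_equal(a.user_samples, b.user_samples)
            and np.array_equal(a.item_samples, b.item_samples)
        )


class TestRunEnsemble:
    def test_pooled_sample_size(self, random_dataset):
        cfg = br.SamplerConfig(
            n_chains=3, sweeps_per_chain=100, burn_in_sweeps=20, sample_interval_sweeps=5
        )
        s = br.run_ensemble(random_dataset, cfg)
        assert len(s) == 3 * 16  # ceil((100-20)/5)
        assert set(np.unique(s.chain_ids)) == {0, 1, 2}

    def test_pooled_variance_not_worse_than_single_chain(self):
        """At equal total sample count, pooling short independent chains
        estimates the posterior at least as precisely as one long chain."""
        ds = br.build_dataset(
            [(0, 0, 1), (0, 1, 2), (1, 0, 1), (2, 1, 2)], K=2, n_users=3, n_items=2
        )
        def estimate(chains, sweeps, seed):
            s = br.run_ensemble(
                ds,
                br.SamplerConfig(
                    n_chains=chains, sweeps_per_chain=sweeps,
                    burn_in_sweeps=20, sample_interval_sweeps=2, seed=seed,
                ),
            )
            return br.posterior(ds, s, [(2, 0)]).probs[0, 0]

        pooled = [estimate(4, 70, 1000 + r) for r in range(150)]  # 4 x 25 samples
        single = [estimate(1, 220, 5000 + r) for r in range(150)]  # 1 x 100 samples
        assert np.var(pooled) <= np.var(single) * 1.3

    def test_pooling_matches_individual_chains(self, random_dataset):
        cfg = br.SamplerConfig(n_chains=2, sweeps_per_chain=80, seed=4)
        pooled = br.run_ensemble(random_dataset, cfg)
        chain0 = br.run_chain(random_dataset, cfg, 0)
        assert np.array_equal(pooled.user_samples[: len(chain0)], chain0.user_samples)


class TestPosterior:
    def test_laplace_rule_single_partition_sample(self):
        # 4 observed ratings (3 like, 1 dislike), everyone in one group
        triples = [(0, 0, 1), (0, 1, 1), (1, 0, 1), (1, 1, 2)]
        ds = br.build_dataset(triples, K=2, n_users=2, n_items=2)
        sample = br.PartitionSample(
            np.zeros((1, 2), dtype=np.int64), np.zeros((1, 2), dtype=np.int64),
            np.zeros(1), np.zeros(1, dtype=np.int64), np.zeros(1, dtype=np.int64),
        )
        post = br.posterior(ds, sample, [(0, 0)])
        assert post.probs[0, 0] == pytest.approx((3 + 1) / (4 + 2))

    def test_empty_data_gives_uniform(self):
        ds = br.build_dataset([], K=4, n_users=3, n_items=3)
        s = br.run_ensemble(ds, br.SamplerConfig(n_chains=2, sweeps_per_chain=60, seed=0))
        post = br.posterior(ds, s, [(0, 0), (2, 1)])
        assert np.allclose(post.probs, 0.25)

    def test_vectors_normalized_on_random_instances(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            n_u, n_i, K = rng.integers(2, 6), rng.integers(2, 6), int(rng.integers(2, 5))
            n_obs = int(rng.integers(1, n_u * n_i))
            flat = rng.choice(n_u * n_i, n_obs, replace=False)
            triples = [
                (int(f // n_i), int(f % n_i), int(rng.integers(1, K + 1))) for f in flat
            ]
            ds = br.build_dataset(triples, K=K, n_users=int(n_u), n_items=int(n_i))
            s = br.run_ensemble(ds, br.SamplerConfig(n_chains=2, sweeps_per_chain=60, seed=trial))
            queries = [(u, i) for u in range(int(n_u)) for i in range(int(n_i))]
            post = br.posterior(ds, s, queries)
            assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)
            assert (post.probs >= 0).all()

    def test_unknown_node_rejected(self, tiny_dataset):
        s = br.run_ensemble(tiny_dataset, br.SamplerConfig(n_chains=1, sweeps_per_chain=20))
        with pytest.raises(KeyError, match="Z"):
            br.posterior(tiny_dataset, s, [("Z", "x")])


class TestPredict:
    def _post(self, rows):
        rows = np.asarray(rows, dtype=float)
        return br.RatingPosterior([(0, 0)] * len(rows), rows)

    def test_map_argmax(self):
        assert br.predict(self._post([[0.1, 0.2, 0.7]]), "map")[0] == 3

    def test_map_tie_breaks_low(self):
        assert br.predict(self._post([[0.5, 0.5]]), "map")[0] == 1

    def test_mean(self):
        p = self._post([[0.5, 0, 0, 0, 0.5]])
        assert br.predict(p, "mean")[0] == pytest.approx(3.0)

    def test_median(self):
        p = self._post([[0.3, 0.2, 0.5], [0.5, 0.2, 0.3], [0.2, 0.2, 0.6]])
        assert br.predict(p, "median").tolist() == [2, 1, 3]

    def test_non_ordinal_rejects_mean(self):
        p = br.RatingPosterior([(0, 0)], np.array([[0.5, 0.5]]), ordinal=False)
        with pytest.raises(ValueError, match="ordinal"):
            br.predict(p, "mean")
        assert br.predict(p, "map")[0] == 1


class TestExhaustivePosterior:
    def test_single_pair_laplace(self):
        ds = br.make_fixture("single").dataset
        post = br.exhaustive_posterior(ds, [(0, 0)])
        assert post.probs[0, 0] == pytest.approx(2 / 3)

    def test_enumerates_bell_product(self):
        assert _bell(3) == 5
        assert len(_set_partitions(3)) == 5
        assert len({canonical_labels(p) for p in _set_partitions(4)}) == 15

    def test_cap_exceeded_reports_pair_count(self):
        ds = br.build_dataset([], K=2, n_users=4, n_items=4)
        with pytest.raises(ValueError, match="225"):
            br.exhaustive_posterior(ds, [(0, 0)], max_pairs=100)

    def test_posterior_sums_to_one(self, random_dataset):
        queries = [(u, i) for u in range(5) for i in range(4)]
        post = br.exhaustive_posterior(random_dataset, queries)
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_exchangeable_under_user_permutation(self):
        triples = [(0, 0, 1), (1, 0, 2), (1, 1, 1), (2, 1, 2)]
        ds = br.build_dataset(triples, K=2, n_users=3, n_items=2)
        post = br.exhaustive_posterior(ds, [(0, 1), (2, 0)])
        perm = {0: 2, 1: 0, 2: 1}
        permuted = br.build_dataset(
            [(perm[u], i, r) for u, i, r in triples], K=2, n_users=3, n_items=2
        )
        post_p = br.exhaustive_posterior(permuted, [(perm[0], 1), (perm[2], 0)])
        assert np.allclose(post.probs, post_p.probs, atol=1e-9)


class TestSamplerAgainstOracle:
    def test_one_group_restriction_recovers_closed_form(self):
        """Sampling restricted to the one-group/one-group partition gives
        exactly (n^r + 1)/(n + K) for randomized count tables."""
        rng = np.random.default_rng(8)
        for trial in range(10):
            K = int(rng.integers(2, 6))
            n_u, n_i = 1, 1  # single nodes: the only partition is one-group
            n_ratings = 1
            ds = br.build_dataset([(0, 0, int(rng.integers(1, K + 1)))], K=K)
            s = br.run_ensemble(ds, br.SamplerConfig(n_chains=1, sweeps_per_chain=30, seed=trial))
            post = br.posterior(ds, s, [(0, 0)])
            counts = np.zeros(K)
            counts[ds.ratings[0] - 1] = 1
            assert np.allclose(post.probs[0], (counts + 1) / (1 + K), atol=1e-12)

    def test_one_group_sample_matches_block_predictive(self, random_dataset):
        """With a hand-built all-one-group sample the estimator is the Laplace
        predictive of the global count table, exactly."""
        sample = br.PartitionSample(
            np.zeros((1, 5), dtype=np.int64), np.zeros((1, 4), dtype=np.int64),
            np.zeros(1), np.zeros(1, dtype=np.int64), np.zeros(1, dtype=np.int64),
        )
        post = br.posterior(random_dataset, sample, [(0, 0)])
        table = br.count_blocks(
            random_dataset, br.Partition(np.zeros(5, dtype=int), np.zeros(4, dtype=int))
        )
        n_r = table.counts[0, 0]
        expected = (n_r + 1) / (n_r.sum() + random_dataset.K)
        assert np.allclose(post.probs[0], expected, atol=1e-12)

    def test_estimator_consistency(self, random_dataset):
        """Error vs the exhaustive oracle shrinks as the sample grows."""
        queries = [(u, i) for u in range(5) for i in range(4)]
        exact = br.exhaustive_posterior(random_dataset, queries).probs
        errs = []
        for sweeps in (50, 500, 5000):
            s = br.run_ensemble(
                random_dataset,
                br.SamplerConfig(n_chains=4, sweeps_per_chain=sweeps, seed=2),
            )
            mc = br.posterior(random_dataset, s, queries).probs
            errs.append(np.abs(mc - exact).max())
        assert errs[2] < errs[0]
        assert errs[2] < 0.02

    def test_detailed_balance_on_empty_instance(self):
        """Transition flows between unlabeled partitions of 3 nodes balance."""
        ds = br.build_dataset([], K=2, n_users=3, n_items=1)
        cfg = br.SamplerConfig(
            n_chains=1, sweeps_per_chain=40_000, burn_in_sweeps=500,
            sample_interval_sweeps=1, seed=6,
        )
        s = br.run_chain(ds, cfg)
        states = [canonical_labels(s.user_samples[k]) for k in range(len(s))]
        flows: dict[tuple, int] = {}
        for a, b in zip(states, states[1:]):
            if a != b:
                flows[(a, b)] = flows.get((a, b), 0) + 1
        for (a, b), n_ab in flows.items():
            n_ba = flows.get((b, a), 0)
            se = np.sqrt(n_ab + n_ba)
            assert abs(n_ab - n_ba) <= 5 * se, f"flow {a}->{b} unbalanced: {n_ab} vs {n_ba}"
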