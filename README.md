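# blockrec

Bayesian prediction of ratings in bipartite user–item networks by averaging
over the full ensemble of stochastic block models.

## The problem and the method

Collaborative filtering asks: given the ratings users have already given to
items, what rating will user *u* give to item *i*?  Most recommenders fit a
single model (a matrix factorization, a neighborhood) and read predictions
off it.  `blockrec` instead treats the family of **stochastic block
models** — users and items simultaneously partitioned into groups, with the
probability of each rating class depending only on the (user group, item
group) pair — and computes the full Bayesian average over *every* partition
pair rather than fitting one.

With ratings taking K classes and a flat prior over models, the per-block
rating probabilities integrate out in closed form (Dirichlet–multinomial),
leaving a posterior over unobserved ratings

    p(r_ui = r | R^O) = (1/Z) Σ_{P_U, P_I} exp(−H(P_U, P_I)) · (n^r_{σu τi} + 1)/(n_{σu τi} + K)

where the sum runs over all partitions of users (P_U) and items (P_I),
n^r_{αβ} counts the observed r-ratings between user group α and item group
β (n_{αβ} their total), σu and τi are the groups of the query pair, and the
Hamiltonian

    H(P_U, P_I) = Σ_{αβ} [ ln Γ(n_{αβ} + K) − Σ_r ln Γ(n^r_{αβ} + 1) − ln Γ(K) ]

is minus the log marginal likelihood of a partition pair: partitions whose
blocks rate homogeneously have low H and dominate the average.  The sum is
intractable (Bell numbers), so it is estimated by Metropolis sampling over
single-node group reassignments, with an over-counting correction
ln N_U!/(N_U−g_U)! + ln N_I!/(N_I−g_I)! that makes labeled-group sampling
uniform over unlabeled partitions.  Exhaustive enumeration over all
partition pairs is included as an exact oracle for small instances.

The package also ships:

* a **synthetic rating generator** with planted groups: each item gets an
  intrinsic quality Q_i ~ U(0,1), each (user group, item group) block an
  a-priori preference π, and p(like) = (1−λ)·Q_i + λ·π, so λ interpolates
  from quality-driven to purely group-driven ratings — together with the
  Bayes-optimal accuracy ceiling E[max(p, 1−p)];
* the classical **baselines** the method is compared against: per-item mean
  (naive), biased Funk-SVD matrix factorization fit by SGD, and item–item
  kNN with adjusted-cosine similarity;
* **evaluation and interpretability tools**: accuracy/MAE benchmarks on
  synthetic λ-grids and on pre-made train/test splits (MovieLens-100k
  dialect), co-classification matrices (probability two users share a group
  across the sampled ensemble), consensus partitions, attribute-correlation
  curves, and genre Jaccard overlap;
* readers/writers for the MovieLens-100k file formats (`u.data`, `u.user`,
  `u.item`, the `u1.base`/`u1.test` splits) and a `blockrec` CLI.

## Worked example

```python
import blockrec as br

# a small block-homogeneous network: 8 users x 8 items in 2x2 blocks,
# each block rated with one constant class, five entries withheld
fx = br.make_fixture("blocks-2x2")

sample = br.run_ensemble(fx.dataset, br.SamplerConfig(n_chains=2, sweeps_per_chain=400, seed=0))
post = br.posterior(fx.dataset, sample, [(u, i) for u, i, _ in fx.heldout])
for (u, i), p, want in zip(post.queries, post.probs, [r for _, _, r in fx.heldout]):
    print(f"user {u} item {i}: p(like)={p[0]:.3f} -> predict {1 if p[0] >= p[1] else 2} (truth {want})")
```

prints

```
user 0 item 1: p(like)=0.912 -> predict 1 (truth 1)
user 2 item 6: p(like)=0.095 -> predict 2 (truth 2)
user 4 item 0: p(like)=0.099 -> predict 2 (truth 2)
user 5 item 3: p(like)=0.098 -> predict 2 (truth 2)
user 7 item 7: p(like)=0.902 -> predict 1 (truth 1)
```

Every withheld rating is recovered: the sampler concentrates on the 2×2
block partition, whose blocks are constant-rated, and the Laplace
predictive (n^r+1)/(n+K) inside each block is nearly certain.  The same
pipeline from the shell:

```bash
blockrec simulate --lam 1.0 --seed 7 --out-dir sim/
blockrec benchmark-model --lambdas 0,0.5,1 --algorithms sbm,naive --replicates 5 \
    --chains 5 --sweeps 5000 --seed 7 --out bench.tsv
```

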