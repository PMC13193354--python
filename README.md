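# hierpop

Hierarchical mixed-stock analysis of diploid multiallelic genotypes.

Migratory freshwater fishes (and many other organisms) are sampled as *mixed
stocks*: a single sampling location pools individuals from several genetically
distinct breeding units.  Pooling leaves a fingerprint — heterozygote deficits
at most loci (the Wahlund effect) — and the underlying structure can be nested:
coarse clusters that themselves split into finer quasi-demes.  `hierpop`
implements the full analysis chain for microsatellite-style codominant markers:

* **I/O & QC** — GenePop / tidy-CSV genotype tables, fragment-length allele
  binning with residual reports, missing-data filtering.
* **Diversity** — N_A, H_O, H_E (and unbiased uH_E), F = 1 − H_O/H_E, PIC,
  private alleles, hypergeometric rarefaction and first-order jackknife
  allelic richness.
* **Equilibrium** — exact Hardy–Weinberg probability test (full enumeration of
  the conditional genotype-array space when small, exact random-pairing Monte
  Carlo otherwise), genotypic linkage-disequilibrium G-test with permutation
  p-values, Holm (sequential Bonferroni) correction.
* **Differentiation** — Jost's D and Hedrick's G″ST from Nei–Chesser-corrected
  heterozygosity components, with jackknife SE and bootstrap CI over loci and
  permutation significance; Smouse–Peakall squared genotype distances; a
  two-level AMOVA φST with permutation p.
* **Clustering** — strict-mixture maximum likelihood via simulated annealing
  (numba-compiled), individual admixture coefficients via EM, replicate
  management, K-selection by the second-order log-likelihood curvature D_LK2
  (with a GST/FIS ratio as a secondary read-out), and a parametric-bootstrap
  panmixia test.
* **Hierarchy** — the recursive first→third-order decomposition: cluster,
  rearrange individuals into the inferred clusters, re-cluster each one, and
  iterate; on nested data this resolves 2 → 4 → 8 clusters.
* **Synthetic data** — a Balding–Nichols nested-deme generator
  (`p_child ~ Dirichlet(p_parent (1−F)/F)` per level) with admixture, location
  pooling, missing-data injection and full ground truth, used by every
  recovery test.

The clustering components are scikit-learn-style estimators
(`MixtureClustering`, `AdmixtureModel`, `HierarchicalDecomposition`) with
`fit`, fitted `labels_` / `Q_` / `loglik_` attributes and `get_params`, so they
compose with sklearn model-selection tooling; thin functional wrappers
(`fit_mixture`, `fit_admixture`, `decompose`, …) cover scripting use.

## Worked example

Simulate two demes separated by drift F = 0.10 (50 diploids each, 15 loci with
15 alleles), scan K = 1–5 with 10 replicate fits per K, and select K by the
curvature of the log-likelihood:

```python
from hierpop import (SimConfig, simulate_hierarchy, run_k_scan, select_k,
                     compare_partitions)

cfg = SimConfig(depth=1, F_levels=(0.10,), n_loci=15,
                alleles_per_locus=(15, 15), n_per_leaf=50, seed=42)
gm, truth = simulate_hierarchy(cfg)
fits = run_k_scan(gm, range(1, 6), n_replicates=10, seed=42)
res = select_k(fits, gm=gm)
print(res.table[["K", "mean_logL", "sd_logL", "DLK2"]].round(2).to_string(index=False))
print("chosen K:", res.chosen_k)
best = max(fits[res.chosen_k], key=lambda f: f.loglik)
ari, acc = compare_partitions(best.labels, truth.leaf_labels())
print(f"ARI = {ari:.3f}, matched accuracy = {acc:.3f}")
```

Output:

```
 K  mean_logL  sd_logL      DLK2
 1   -5849.18     0.00       NaN
 2   -5207.07     0.00 488933.12
 3   -5053.88     5.30      2.36
 4   -4913.19     5.45      4.55
 5   -4797.30     4.29       NaN
chosen K: 2
ARI = 1.000, matched accuracy = 1.000
```

The log-likelihood jumps by ~640 units from K = 1 to K = 2 and then flattens;
the normalized second difference D_LK2 peaks sharply at K = 2 (its huge value
reflects zero replicate variance at K ≤ 2), and the K = 2 assignment recovers
the true demes exactly (adjusted Rand index 1.0).

The full recursive decomposition is one call:

```python
from hierpop import benchmark_config, decompose, order_summary

gm, truth = simulate_hierarchy(benchmark_config(seed=0))   # 8 nested demes
tree = decompose(gm, seed=0)        # panmixia-gated, K by D_LK2, 3 orders
tree.to_frame()                     # individual -> order1/order2/order3 path
order_summary(tree, gm)             # per-order diversity & differentiation
```

On this benchmark the tree splits 2 → 4 → 8 across the three orders and the
leaf partition matches the true demes with ARI ≈ 0.85.

There is also a CLI for shell use (`hierpop simulate`, `hierpop diversity`,
`hierpop hwe`, `hierpop diff`, `hierpop amova`, `hierpop hierarchy`,
`hierpop all`, `hierpop report --config run.yaml`); every run is fully seeded
and writes a manifest, CSV/JSON tables and a Markdown report.

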