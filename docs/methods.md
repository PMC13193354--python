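# Methods

`hierpop` implements a hierarchical mixed-stock analysis for diploid,
multiallelic, codominant markers (microsatellites): within-sample diversity and
equilibrium diagnostics, among-sample differentiation, maximum-likelihood
clustering, and a recursive order-by-order decomposition that searches for
nested genetic structure.  Because studies of this kind often deposit marker
resources but not the genotype matrix itself, the package ships a synthetic
nested-deme generator with full ground truth, and every claim the test suite
makes is made against that generator or against closed-form oracles.

## The data model

A `GenotypeMatrix` holds unordered diploid allele pairs per (individual, locus),
with opaque integer allele labels (allele classes).  A call in which only one
allele could be scored is recorded as *half-missing* and treated as fully
missing by every statistic: the pipeline's tests and distances are
genotype-level, and a partial call would require a separate likelihood for the
scoring process, which is out of scope.  Per-locus sample sizes therefore count
fully genotyped individuals only.

GenePop (2- and 3-digit codes) and a tidy CSV are the interchange formats.
Fragment-length binning snaps raw sizes to the repeat-unit grid
`offset + k * motif` whose offset (searched on [0, motif) at 0.1 bp) minimizes
total squared deviation, and reports per-length residuals so a human can review
ambiguous bins; no automatic override of odd bins is attempted.

## Synthetic nested demes

The generator encodes the hypothesis under test: a balanced binary hierarchy of
breeding demes, each level adding an independent pulse of drift.  Drift uses the
Balding–Nichols construction, `p_child ~ Dirichlet(p_parent (1-F)/F)`, one
interpretable `F` per level, so nesting composes in closed form and no
generation-by-generation simulation is needed.  Ancestral frequencies are
symmetric-Dirichlet with concentration `theta = 1` (flat on the simplex); with
13–31 alleles per locus this yields expected heterozygosity near 0.9, matching
highly polymorphic microsatellite panels.  Individuals are Hardy–Weinberg draws
within their leaf deme, or, in admixed mode, draw each gene copy from a leaf
chosen by an individual ancestry vector `Q ~ Dirichlet(alpha)`.

Two canned configurations:

* **survey emulation** — depth 3 (8 leaves), `F = (0.12, 0.08, 0.05)`, 15 loci
  with 13–31 alleles, 18.6% missing calls, and four sampling locations of sizes
  20/40/40/40 that each pool two leaves from opposite sides of the top split
  (maximal Wahlund mixing).
* **recovery benchmark** — the same hierarchy with 16 individuals per leaf and
  complete data, used for the clustering-recovery tests.

The per-level `F` values are calibrated only to make recovery feasible at these
sample sizes; real drainage systems need not be balanced, binary, or
equal-drift.  The generator has no mutation model (alleles lost to drift stay
lost), no null alleles, and no genotyping-error process, so passing tests
demonstrate the statistical machinery, not robustness to scoring artefacts.

## Diversity and equilibrium

Expected heterozygosity is the plug-in `H_E = 1 - sum p^2` (the unbiased
`2N/(2N-1)` variant is reported alongside); `F = 1 - H_O/H_E` is undefined at
monomorphic loci; PIC follows the classic codominant definition.  Rarefied
allelic richness uses the exact hypergeometric form
`E[A_g] = sum_a [1 - C(N-N_a, g)/C(N, g)]` on gene copies — "retaining 20
samples" of diploids is interpreted as `g = 40` gene copies, since richness is a
gene-copy property.  The first-order jackknife richness is over individuals,
with the Heltshe–Forrester variance.

The Hardy–Weinberg test is the conditional probability exact test.  The
conditional distribution of genotype arrays given allele counts is enumerated
when a cheap stars-and-bars bound certifies the space is at most 1e5 arrays;
otherwise it is sampled by uniform random pairings of the 2n gene copies, which
draw exactly from the conditional null (no Markov-chain burn-in to tune or
verify), with the add-one estimator `p = (1+hits)/(1+B)` so p is never zero.
The probability test is two-sided; the direction of a deviation is read off the
sign of `F` rather than from a one-sided deficit test.  Linkage disequilibrium
is a genotypic G-test with significance by permuting one locus's genotype column
(add-one estimator again).  With very sparse genotype-by-genotype tables the
permutation test is valid but conservative (ties are counted as hits);
calibration checks therefore use designs with adequately occupied tables
(3 allele classes at n = 50 give empirical size ~0.05 at alpha = 0.05).
Multiple testing uses Holm's step-down (sequential Bonferroni) everywhere.

A power note for Wahlund scenarios: pooling two demes whose drift parameter is
`F` produces a pooled-sample heterozygote deficit of size `F-hat ~ GST`
between the demes — and for hypervariable markers `GST` saturates far below
`F` (the effect that motivates Jost's D).  At drift `F = 0.15` and 13-31
alleles, realized `GST ~ 0.065`, and the exact test at n = 80 rejects at about
63% of loci on average, essentially all on the deficit side.

## Differentiation

Jost's `D = K/(K-1) (H_T-H_S)/(1-H_S)` and Hedrick's standardized
`G''ST = K (H_T-H_S)/((K H_T - H_S)(1-H_S))` are computed from Nei–Chesser
small-sample-corrected heterozygosity components by default (plug-in mode exists
for closed-form tests).  Multi-locus values combine across-locus *means of H_S
and H_T*, not means of per-locus ratios, which keeps near-monomorphic loci from
destabilizing the estimate.  Uncertainty: delete-one-locus jackknife SE and
percentile bootstrap CI over loci; significance: permutation of individual group
labels, 999 by default.

Genotype distances are the squared codominant distances
`d^2 = 1/2 |c1 - c2|^2` on allele-count vectors, giving the standard
0/1/2/3/4 table; pairs missing at some loci are rescaled by `L/L_obs`
(unbiased under missing-completely-at-random, no imputation model).  The
two-level AMOVA computes `SS_total = (1/N) sum d^2`, per-group `SS_within`,
variance components via `n0`, and `phi_ST = s2_among/(s2_among+s2_within)`,
reported raw (negative estimates are floored only in the percent display), with
label-permutation significance.

### Standardized indices on pooled clusters

One property matters when reading order-wise trends on a decomposition:
`D` and `G''ST` divide by `(1 - H_S)`, so clusters that are internally
structured (pools of several demes, hence Wahlund-inflated `H_S`) get
*inflated* standardized differentiation.  Under the default benchmark profile —
largest drift pulse at the top level, `F = (0.12, 0.08, 0.05)` — an
infinite-sample oracle on true pool frequencies shows mean pairwise `D` and
`G''ST` *decreasing* from first- to third-order clusters (G''ST about
0.70 -> 0.63 -> 0.60) even though raw `GST = (H_T-H_S)/H_T` rises slightly and
within-cluster `H_E` falls.  With an increasing-drift profile
(`F = (0.05, 0.08, 0.12)`, finer breeding units drifting harder) all three
indices rise with order (oracle G''ST 0.56 -> 0.64 -> 0.68): the direction of
the trend is a property of the drift profile, not of the method.

On the benchmark the inferred partitions track the true pools closely enough
that their differentiation values coincide to three decimals, so the effect
above is a property of the statistics, not of estimation error.  Order
summaries report `D`, `G''ST` and raw `GST` side by side; on the default
benchmark the reliable order-wise signatures are falling within-cluster `H_E`
and `N_A`, rising HWE conformity and rising raw `GST`, while rising
*standardized* differentiation additionally requires drift to intensify toward
finer levels.

## Clustering

**Strict mixture.**  The profile log-likelihood of a hard assignment `z` is
`sum_kla n_kla log p_kla` at the within-cluster frequency MLE smoothed by a
Jeffreys pseudo-count `beta = 0.5` per allele (finite for empty clusters).  It
is maximized by Metropolis simulated annealing over single-individual
reassignments: initial temperature equal to the SD of per-individual
log-likelihood contributions (scale-free), geometric cooling x0.95 per sweep,
at most 200 sweeps, stop after 5 acceptance-free sweeps.  The best state ever
visited is returned, so the result is never worse than the initial one.  The
move delta is O(loci) and the inner loop is compiled (numba), making a fit on
~100 individuals a few milliseconds.

**Admixture.**  Each individual has ancestry fractions `q_i` on the K-simplex;
a gene copy of allele `a` at locus `l` has probability `sum_k q_ik p_kla`.  EM:
copy responsibilities in the E-step, simplex-normalized responsibility sums in
the M-step (missing calls skipped).  Initialization softens a mixture solution
to 0.9 on the winning cluster (random Dirichlet otherwise); non-finite
likelihoods trigger a logged random restart.  Defaults `tol = 1e-5` on the
log-likelihood increment and `max_iter = 300` resolve K-selection differences
(hundreds of log-units) with margin; tests of EM monotonicity pass `tol = 1e-8`
explicitly.  Ties in the hard assignment `argmax q` break toward the lowest
cluster index.

**K-selection.**  For each K in the assayed range, R replicate fits (default 10)
give mean `L(K)` and SD.  The selector is the second-order rate of change
`D_LK2(K) = |L(K+1) - 2L(K) + L(K-1)| / max(SD(K), 1e-3)`; the SD floor exists
because replicate families frequently have zero variance.  Ties break toward
smaller K; if every curvature is zero the result is flagged and K = 1 is
returned for panmixia inspection.  A `GST/FIS` ratio over the inferred hard
clusters is reported as a secondary estimator only — exact published
definitions of the original software's normalization are not available, so
both our definitions are declared in the output metadata and the curvature
criterion stays authoritative.

**Panmixia.**  The informal practice of eyeballing log-likelihoods against
K = 1 is replaced by a reproducible parametric bootstrap: the statistic is the
best K = 2 profile log-likelihood minus the K = 1 log-likelihood; B datasets
simulated from the pooled-frequency MLE under Hardy–Weinberg (with the observed
missing pattern) are refitted identically, giving an exchangeable null and an
add-one p.  Note the resolution constraint `1/(B+1) < alpha`: the default
B = 49 supports alpha = 0.05.

## Hierarchical decomposition

Starting from all individuals: test panmixia (stop if p >= alpha), stop if
n < `n_min` (default 15 — a K = 2 split below ~8 individuals per cluster is
unidentifiable with 15 loci), otherwise scan K = 1..Kmax with Kmax from the
per-order schedule {1: 14, 2: 7, 3: 4} capped at n // 5, choose K by D_LK2,
hard-assign members by maximum ancestry, and recurse to the third order.
Individuals pass between orders by hard assignment — admixed individuals are
not split fractionally, matching the rearrangement-into-clusters procedure the
analysis models.  Every node stores its K-scan table, best fit, panmixia p and
stop reason; the tree serializes to nested JSON plus a flat per-individual
cluster-path CSV, and `order_summary` emits the per-order diversity /
differentiation / HWE-conformity table.  Recovery is scored by adjusted Rand
index and by accuracy under maximum-weight one-to-one label matching.

## Problem sizes and determinism

Default problem sizes keep the full validation suite desk-scale: the recovery
benchmark uses 128 individuals x 15 loci with 10 replicate fits per K and a
49-replicate panmixia bootstrap (one decomposition approximately 40 s on one
core); calibration studies use 1000 null simulations.  All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; identical seeds
give byte-identical outputs end to end, and the pipeline writes no timestamps
into data files (timings go to the run log only).

## Known limitations

* No stepwise-mutation model, null alleles, allelic dropout or stutter; the
  generator cannot probe robustness to those artefacts.
* The strict-mixture annealer is a stochastic global-search heuristic; replicate
  scatter at large K is expected and is exactly what D_LK2's SD normalization
  consumes.
* The admixture likelihood assumes linkage equilibrium within clusters and
  ignores genotyping uncertainty.
* Half-missing calls discard the scored allele rather than modelling it.
* AMOVA is two-level only; a three-level design (locations within orders) is
  not implemented.
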