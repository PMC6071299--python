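# Methods

## Problem setting

Given a genes × samples expression matrix `X` with no sample labels,
the package ranks genes by how strongly they discriminate latent sample
groups (e.g. genotype series in a disease model), on the premise that
genes tracking the latent structure are the disease-associated ones.
The core is consensus-guided unsupervised feature selection (CGUFS)
wrapped in a bagging ensemble (ECGUFS).

## Model

CGUFS minimises, over the consensus indicator `H*` (samples × K, one 1
per row), center matrices `C` and `G`, and the feature-selection matrix
`Z` (genes × K):

    J(H*, C, G, Z) = α‖B − H*C‖²_F + ‖XᵀZ − H*G‖²_F + β‖Z‖₂,₁

* `B` stacks `r` independent K-means partitions of the samples
  ("basic clusterings"); the first term pulls `H*` toward a consensus
  of them.
* The second term regresses the low-dimensional gene projection `XᵀZ`
  onto the cluster structure, so `Z` selects genes that explain the
  pseudo-labels.
* The ℓ2,1 penalty `‖Z‖₂,₁ = Σᵢ‖Z_i·‖₂` drives whole rows of `Z` to
  zero — row sparsity is what makes the row norms usable as per-gene
  weights `w_i = ‖Z_i·‖₂`.

### Alternation

1. **Consensus step.** With `Z` fixed, the first two terms are the
   within-cluster sum of squares of K-means on the augmented matrix
   `U = [√α·B | XᵀZ]`: squared Euclidean distances on the left block
   contribute exactly `α‖B − H*C‖²`. One K-means pass on `U` updates
   `H*`; its centers split at the block boundary into `C` (rescaled by
   1/√α) and `G` (the trailing K columns). A strict mode scaling the
   block by `α` instead of `√α` is available for comparison, but only
   the `√α` form makes the K-means equivalence an identity, so it is
   the default.
2. **Z step.** With `H*`, `G` fixed, the nonsmooth penalty is handled
   by iteratively reweighted least squares: solve
   `(XXᵀ + βF)Z = XH*G`, `F = diag(1/(2‖Z_i·‖₂))` built from the
   previous iterate. Row norms inside `F` are clamped at ε = 1e−8
   (the reweighting is undefined at zero). The system is solved as an
   SPD linear solve, never an explicit inverse. For β = 0 the update
   degenerates to the normal equations of `‖XᵀZ − H*G‖_F`; since
   `XXᵀ` is singular whenever genes outnumber samples, that branch
   uses the minimum-norm least-squares solution, which satisfies the
   normal equations exactly.

**Monotonicity.** The consensus step warm-starts Lloyd's algorithm
from the previous partition's centers on the new `U`, so its objective
cannot exceed the previous iteration's value; the IRLS step is a
standard majorise–minimise update of the penalised regression. The
outer objective trace is therefore non-increasing (the ε-clamp can in
principle perturb this by O(ε) for rows crossing the clamp; measured
violations are zero at the test scales). Iteration stops when the
relative objective change drops below `tol` (default 1e−6) or at
`max_iter` (default 100, warning on non-convergence).

**Initialisation.** `H*` by K-means consensus on `B` alone; `Z` with
uniform(0, 1) entries; K-means seeding is k-means++ with
`restarts`-fold best-of (default 10 for standalone runs, a single
warm-started pass inside the alternation). Empty clusters are repaired
by moving the point farthest from its center into the empty cluster,
keeping every indicator row-stochastic with all K clusters present.

### Ensemble

`b` bags of `c` samples are drawn with replacement (defaults b = 20,
c = the sample count). Each bag is re-z-scored — the optimisation
assumes standardised gene rows and a bootstrap column draw no longer
is — and fitted by a full CGUFS run with fresh basic clusterings (bags
differ in their sample draw, so `B` cannot be shared). Each bag's
ranking is scored by its ROC AUC `a_i` over the labeled evaluation
genes, and the final weights are the linear combination
`W_final = Σ a_i W_i`. Per-bag seeds are split from the master seed
with `numpy.random.SeedSequence`, so `(seed, b)` determines every
draw. Bags with `a_i < 0.5` are kept (the combination is applied
literally); a flag can drop them. An unweighted mode (`a_i = 1`)
supports fully label-free use — the AUC weighting is the one place
the otherwise unsupervised pipeline consumes labels.

## Parameters

| parameter | default | meaning |
|---|---|---|
| K | 6 | number of sample clusters (e.g. genotype groups) |
| r | 100 | basic clusterings stacked into B |
| α | 1e4 | weight of the consensus term (unitless) |
| β | 1 | ℓ2,1 sparsity weight (unitless) |
| b | 20 | bootstrap bags |
| c | n. samples | samples per bag |
| tol | 1e−6 | relative objective change to declare convergence |
| max_iter | 100 | outer iteration cap |

Preprocessing defaults follow the order: drop genes with any zero
value → rescale each sample to unit total → keep the 4000 most
variable genes → z-score each gene (population-σ convention;
constant rows map to zero with a warning). Variance ties break by
input order.

## Synthetic data

`SyntheticSpec`/`generate` emulate a replicated genotype series:
`s` samples in `K_true` balanced groups; `n_informative` genes whose
group means follow a ladder with step `effect·noise_sd`, each gene
receiving a random permutation of the ladder so informative genes are
not collinear; the remaining genes are pure Gaussian noise. Evaluation
labels mark the informative genes positive and an equally sized random
subset of noise genes negative. A `counts` mode pushes the same
structure through a lognormal-baseline negative-binomial sampler to
exercise the zero-filter/normalisation path end to end.

What this emulates — and does not: planted spherical Gaussian groups
are the cleanest case for K-means; real RNA-Seq has correlated genes,
library-size artefacts, and cluster structure far weaker than any
`effect ≥ 2` setting here. Passing recovery tests on this generator
shows the optimisation machinery works, not that the method attains
any particular accuracy on real tissue data.

A consequence worth stating explicitly: on this generator the bagging
ensemble does **not** reliably improve over a single full-sample run.
A bootstrap bag of c = s = 48 samples keeps ~63% distinct samples
(~5 of 8 replicates per group), so each bag's consensus clustering —
and hence its ranking — is strictly noisier than a full-sample run's;
the AUC-weighted combination recovers most but not always all of the
gap, and re-drawn bags add seed-to-seed variance that can exceed the
single run's initialisation variance. The ensemble's advantage is
expected in the regime where single-run initialisation noise dominates
(weak, ambiguous cluster structure), which this generator does not
reproduce at any tested effect size. The stability comparison in the
acceptance suite documents this honestly rather than tuning around it.

## Evaluation machinery

ROC/PR curves sweep the ranking restricted to labeled genes, grouping
equal weights into one threshold step; AUC is trapezoidal (equal to
the Mann–Whitney statistic with half credit for ties — the test
oracle), AUPR uses step-interpolated precision (conventions differ
across software; the step convention is fixed and documented here).
Stability is quantified by top-k coincidence: `|top-k(A) ∩ top-k(B)|/k`
for all run pairs. The classification check is a linear SVM (C = 1.0)
with stratified k-fold cross-validation on the selected feature genes.

## Problem sizes in the test and acceptance runs

The shipped tests and `scripts/acceptance.py` use desk-scale settings
chosen as the package's own defaults for reproducible runs: g = 500,
s = 48, K = 6, 50 informative genes, effect 2, r = 20, b = 10, with
10 seeded repetitions. These preserve the design's shape (48 samples,
6 groups) at a gene count where a full ensemble run takes seconds.

## Known limitations

* Dense linear algebra throughout; the design point is g ≲ 10⁴ genes.
* K must be supplied; no model selection for K, α, β, r.
* The AUC bag weighting needs labeled genes; the unweighted mode is
  the only fully unsupervised path.
* Ranking stability across seeds is moderate by construction (random
  Z initialisation, random bags); fixed seeds give bit-reproducible
  runs.
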