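# ecgufs

Ensemble consensus-guided unsupervised feature selection for ranking
disease-associated genes from expression matrices.

## What it does

Given a genes × samples expression matrix with *unlabeled* samples,
`ecgufs` ranks every gene by how strongly it discriminates the latent
sample groups (genotypes, disease stages, …). It alternates two steps
to minimise

    α‖B − H*C‖²_F + ‖XᵀZ − H*G‖²_F + β‖Z‖₂,₁

where `B` stacks `r` K-means "basic clusterings" of the samples, `H*`
is the consensus cluster indicator, and `Z` is a row-sparse
feature-selection matrix: a K-means pass on the augmented matrix
`U = [√α·B | XᵀZ]` updates `H*` and `G`, and an iteratively
reweighted least-squares solve `Z = (XXᵀ + βF)⁻¹XH*G` with
`F = diag(1/(2‖Z_i·‖₂))` updates `Z`. Gene `i`'s weight is
`w_i = ‖Z_i·‖₂`. A bagging layer repeats this on `b` bootstrap sample
bags, scores each bag's ranking by its ROC AUC `a_i` against a small
labeled evaluation gene set, and combines `W_final = Σ a_i W_i`.

The package also ships the evaluation machinery for ranked gene lists
(ROC/PR curves, AUC/AUPR, top-k coincidence matrices, a linear-SVM
cross-validation check) and a synthetic-data generator with planted
sample clusters and discriminative genes, so the whole pipeline is
testable without any external dataset. See `docs/methods.md` for the
full model description and design choices.

## Worked example

```python
import ecgufs

# synthetic 500-gene, 48-sample matrix: 6 planted sample groups,
# 50 discriminative genes (positive labels) among 450 noise genes
spec = ecgufs.SyntheticSpec(g=500, s=48, K_true=6, n_informative=50,
                            effect=2.0, seed=0)
X, labels, groups = ecgufs.generate(spec)
Xz = ecgufs.zscore_genes(X)

# single run
W, state, H = ecgufs.run_cgufs(Xz, K=6, r=20, alpha=1e4, beta=1.0, seed=1)
print(f"converged in {state.n_iter} iterations,",
      f"ranking AUC {ecgufs.bag_auc(W, labels):.3f}")

# bagged ensemble (10 bags, AUC-weighted combination)
W_final, bags = ecgufs.run_ecgufs(Xz, labels, K=6, r=20, b=10, seed=1)
ranked = ecgufs.rank_genes(W_final)
curves = ecgufs.roc_pr_curves(ranked, labels)
print(f"bag AUCs {[round(b.auc, 2) for b in bags[:3]]}...,",
      f"ensemble AUC {curves.auc:.3f}, AUPR {curves.aupr:.3f}")
print("top 5 genes:", ranked.top(5))
```

Output:

```
converged in 4 iterations, ranking AUC 0.957
bag AUCs [0.84, 0.79, 0.74]..., ensemble AUC 0.929, AUPR 0.928
top 5 genes: ['G00040', 'G00038', 'G00045', 'G00037', 'G00002']
```

The single-run AUC (0.957) says the planted discriminative genes
occupy the top of the ranking almost perfectly; individual bootstrap
bags are noisier (AUC ≈ 0.74–0.84 — each bag sees only ~63% distinct
samples) and the AUC-weighted combination recovers most of that gap
(0.929). All five top genes are planted positives (`G00001`–`G00050`).

## Command line

```sh
ecgufs simulate --out sim/ --genes 500 --samples 48 --clusters 6 \
    --informative 50 --effect 2 --seed 0
ecgufs rank --expression sim/expression.tsv --labels sim/gene_labels.tsv \
    --out run/ --k 6 --r 20 --bags 10 --seed 1
ecgufs evaluate run/ranked_genes.tsv --labels sim/gene_labels.tsv \
    --out eval/ --top-k 50
```

Every run writes a `manifest.json` with the resolved options, seed and
library versions; the same config + seed reproduces outputs
byte-identically.

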