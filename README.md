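# tensorfe

Tensor-decomposition-based unsupervised feature extraction for two omics
layers measured on the same samples — typically mRNA and miRNA expression
from a tumor/normal cohort.

## The problem

Given an mRNA layer `x_ij` (i = 1..N genes, j = 1..M samples) and a miRNA
layer `x_kj` (k = 1..K miRNAs), we want a *small* set of genes and miRNAs
whose expression jointly tracks a phenotype (e.g. tumor vs normal), selected
without ever using the labels to build the features.  Supervised per-feature
tests (t-test and friends) select thousands of features at conventional FDR
thresholds and replicate poorly across cohorts; an unsupervised decomposition
that concentrates the shared class-driven variation into one component
produces compact, reproducible signatures.

## The method

The two layers define an implicit 3-way tensor `x_ijk = x_ij · x_kj`.
Materializing it is infeasible (N·M·K ≈ 5×10⁹ for a typical TCGA cohort), so
it is collapsed over the sample mode,

    x_ik = Σ_j x_ij x_kj  =  (A Bᵀ)_ik ,

and the N×K collapsed matrix is factorized by SVD,

    x_ik = Σ_l λ_l u_li u_lk ,

which is the higher-order-SVD route to a Tucker factorization of the implicit
tensor, restricted to the two feature modes.  Each layer is then projected
onto its feature singular vectors to recover sample-mode coordinates,

    u^mRNA_lj = Σ_i x_ij u_li ,   u^miRNA_lj = Σ_k x_kj u_lk .

Class labels enter only now: the component whose two projections best
separate the classes (Welch t-test, both layers) and agree across layers
(Pearson correlation) is chosen — with dominant feature baselines this is
typically component l = 2, component 1 carrying mean expression.  Features
are scored on that component's vector by

    P_i = Pr[ χ²₁ > (u_li / σ_l)² ] ,

where σ_l is the standard deviation of the component vector, and features
with Benjamini–Hochberg-adjusted P < 0.01 are selected.

The package also provides the single-layer PCA variant (gram-matrix
eigenvectors as feature scores, the same χ²/BH selection), a supervised
Welch-t baseline, cross-layer pair-correlation analysis of the selected
features, cross-dataset concordance testing (2×2 confusion table + Fisher
exact test), and a seeded synthetic paired-omics generator with planted
signal for validation.

## Worked example

```python
from tensorfe import TensorFE, generate_dataset, recovery_metrics

ds = generate_dataset()                     # planted synthetic dataset
model = TensorFE(ds.layer_a, ds.layer_b, ds.annotation)
res = model.fit()
print(res.summary())
```

```
Tensor-decomposition feature extraction
=======================================================
layers: mRNA (2000 features) x miRNA (300 features), 60 samples
components: 10

  l     lambda   t_p(A)      t_p(B)      PCC
  1    2.185e+04 0.16        0.507       -0.134
  2         3833 2.72e-62    4.48e-62    +0.995
  ...

chosen component (auto): l = 2
selected at BH-adjusted P < 0.01: 50 mRNA, 20 miRNA
```

Component 1 (largest λ) captures feature baseline expression and does not
separate the classes; component 2 separates them overwhelmingly in both
layers (Welch P ≈ 10⁻⁶²) with near-perfectly correlated projections
(PCC = 0.995).  Selection on component 2 recovers the planted signatures:

```python
m = recovery_metrics(res.selected_ids("mRNA"), ds.truth_a)
print(m)   # {'precision': 1.0, 'recall': 1.0, 'f1': 1.0}
```

The same pipeline runs from the shell:

```bash
tensorfe simulate --out data/ --seed 11
tensorfe run --method td --mrna data/layer_a.tsv --mirna data/layer_b.tsv \
             --labels data/labels.tsv --out results/
tensorfe pairs --mrna data/layer_a.tsv --mirna data/layer_b.tsv \
               --scores results/feature_scores.tsv --out results/pairs.tsv
```

Real data enter as plain features-by-samples TSV or GEO series-matrix files
(`--input-format geo`), with a two-column `sample_id  label` annotation.

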