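# Methods

## Model and procedure

Two expression layers on shared samples, A (N×M) and B (K×M), define an
implicit rank-3 tensor `x_ijk = a_ij b_kj`.  The pipeline:

1. **Alignment.** Both layers are restricted to the intersection of their
   sample IDs, ordered lexicographically.  Sorting is a deterministic choice;
   any fixed order gives the same factorization up to column permutation of
   the projections.
2. **Preprocessing.** Features with non-finite values or zero variance are
   dropped.  Each sample column is then centered and rescaled to mean 0 and
   sum of squares equal to the number of features.  This standardization is
   required by the PCA route's gram-matrix formulation; we apply it before
   the tensor route as well (switchable off) because the χ² feature scoring
   implicitly compares component entries to a Gaussian null, which per-sample
   standardization makes far more plausible.  An optional `log2(x + offset)`
   transform (default off) accommodates count-like RNA-seq units; microarray
   intensities are typically already log-scale.
3. **Collapse + SVD.**  `x_ik = Σ_j a_ij b_kj = (A Bᵀ)_ik`, then the top-L
   SVD of the N×K matrix.  The full Tucker core of the implicit tensor is
   never computed — the collapsed matrix *is* the tractable surrogate, and no
   accuracy claim about the full core is made.  Default `L = min(10,
   min(N, K))`: only low-index components are ever biologically inspected.
4. **Component choice.**  Per component: Welch (unequal-variance) t-test of
   each layer's sample projections between the two classes, plus the Pearson
   correlation between the layers' projections.  `auto` picks the component
   minimizing `max(t_p_A, t_p_B)` — it must separate classes in *both*
   layers — with ties to the smaller index.  A manual override mirrors
   choosing by inspection.
5. **Selection.**  `P = Pr[χ²₁ > (u/σ)²]` with σ the standard deviation of
   the component vector itself (sample, m−1 denominator by default;
   population optional).  One degree of freedom is the only choice consistent
   with squaring a single standardized Gaussian coordinate.  BH adjustment,
   then strict `adjusted P < α` with α = 0.01.

The PCA variant runs per layer: PC scores over features are gram-matrix
eigenvectors (computed via the SVD of the standardized layer, never forming
the N×N gram matrix for large N), PC loadings over samples are `v = Xᵀu`,
the component is chosen by the loadings t-test independently per layer, and
the same χ²/BH chain scores the PC-score entries.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `L` | min(10, min(N, K)) | components extracted |
| `alpha` | 0.01 | BH-adjusted selection threshold (strict `<`) |
| `sd_mode` | sample | denominator of σ in the χ² statistic |
| `standardize` | on | per-sample mean-0 / SS-N normalization |
| `log2_offset` | off | optional log2(x + offset) pre-transform |

## Numerical choices

- SVD sign ambiguity is fixed by orienting each component so the
  largest-magnitude entry of the layer-A singular vector is positive;
  diagnostics (t-test P, |PCC|) are orientation-invariant by construction.
- Dense LAPACK SVD up to `min(N, K) = 2000`; a truncated Lanczos solver with
  a fixed start vector (determinism) above.  Both satisfy the same
  reconstruction and orthonormality contracts.
- Negative PCA eigenvalues arising from round-off are clamped to zero.
- Fisher's exact test is two-sided by the probability-mass criterion; both
  the sample (cross-product) odds ratio — infinite when the off-diagonal
  product is zero — and the conditional-MLE odds ratio are reported, since
  the two differ noticeably in heavily unbalanced tables.
- Degenerate inputs: zero-variance component vectors abort scoring;
  zero-variance features in the pair-correlation grid are flagged and
  excluded from the BH family; degenerate 2×2 margins return P = 1 with
  undefined odds ratios and a flag.
- BH runs over each scoring family jointly (all features of one layer; the
  full mRNA×miRNA pair grid).

## Synthetic data generator

Each layer is `x_ij = μ_i + δ·s_i·c_j·[i planted] + ε_ij` with feature
baselines `μ_i ~ N(μ₀, baseline_sd²)`, planted signs `s_i ∈ {±1}`, class
scores `c_j = ±1`, and iid Gaussian noise.  Both layers share the class
scores, so the planted signal is the cross-layer structure the method is
built to find.  With `μ₀ = 5` well above zero, baseline magnitudes dominate
component 1 and the class contrast lands on component 2 — the configuration
observed on real tumor cohorts.  Defaults: N = 2000, K = 300, 30 cases + 30
controls, 50 + 20 planted features, δ = 2, noise σ = 1, chosen as a
desk-scale cohort with per-feature effect size (2δ/σ = 4 between classes)
typical of strong tumor/normal expression differences.  A preset mirrors the
253/71 imbalance of a real kidney-carcinoma cohort; the balanced 30/30
default keeps test statistics stable at small M.  An optional lognormal mode
exponentiates the field for skewed positive values.

What the generator does *not* emulate: sequencing-depth and library-size
variation, batch effects, correlated noise between features, miRNA→target
network topology, or class-label noise.  Passing recovery tests therefore
demonstrates correctness of the algebra and calibration of the selection
chain under the model's own assumptions — not performance on real cohorts,
where normalization choices and confounders dominate.

## Problem sizes used in validation

Brute-force tensor equivalence is checked on instances up to 8×6×7, where
the explicit triple-loop tensor is cheap; statistical oracles use closed
forms (χ²₁ tail = erfc(√(x/2))), an O(m²) BH re-derivation, and full
hypergeometric enumeration for all 2×2 tables with margins ≤ 12.  Recovery
and null-calibration runs use the default generator dimensions (2000 + 300
features, 60 samples; 10 replicates for the null), which the pipeline
processes in well under a second each.

## Known limitations

- The collapsed-matrix SVD is a surrogate for the full tensor HOSVD; the two
  feature-mode factor sets coincide only up to the sample-mode collapse, and
  the quality of the approximation is not quantified here.
- Selection P-values are descriptive ranking devices: component entries are
  not literally iid Gaussian under the null, so the χ² tail is a calibration
  convention rather than an exact error rate (the null simulations show it
  is conservative at the defaults).
- On repeated synthetic draws the smaller layer's recall fluctuates
  (typically 0.85–1.0 at the defaults) because only 20 planted features face
  a 300-feature BH family; precision stays at 1.0.
- Cross-dataset concordance takes pre-matched feature ID sets; mapping
  between platform identifier schemes is out of scope.
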