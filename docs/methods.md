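# Methods

## Model

`scired` decomposes a cell × gene count matrix Y (n × g) as

    Y = C β + F A + U H + ε

where C (n × p) holds known technical covariates (library size, protocol,
batch, ...), F/A are factors annotated to covariates, U/H are unannotated
factors, and ε is noise. The solution is two-step:

1. **Residualization.** Each gene's counts are fitted by a Poisson GLM with
   log link on the technical design C (statsmodels IRLS, tolerance 1e-8 on
   the deviance, 50-iteration cap). Pearson residuals
   r = (y − μ̂)/√μ̂ (Poisson: Var = mean) form the working matrix; response
   (y − μ̂) and deviance (sign(y − μ̂)·√(2(y log(y/μ̂) − (y − μ̂))),
   0·log 0 := 0) residuals are available for robustness checks. Residuals
   are never clipped or rescaled afterwards. All-zero genes get their
   fitted mean floored at 1e-10 and a `converged=False` flag instead of an
   error. Genes expressed in fewer than 3 cells can be dropped before
   fitting (`CountMatrix.filter_genes`, configurable); no other QC is
   applied.

2. **Factorization.** The residual matrix is centered per gene and
   decomposed by SVD; scores are U·S, loadings the right singular vectors.
   The top-k loadings (default k = 30; k = 10 suffices for the synthetic
   benchmark) are varimax-rotated: Kaiser row-normalization on by default,
   the classical iterative-SVD update, stopping when the trace criterion
   improves by less than 1e-5 (cap 1000 iterations). The rotation is
   orthogonal (RᵀR = I to machine precision) and never decreases the
   Kaiser criterion. Promax (oblique) powers the row/column-normalized
   varimax loadings element-wise (default cube, sign preserved), fits
   R = (LᵀL)⁻¹LᵀP by least squares, and normalizes the rotation columns to
   unit sum of squares; the returned rotation composes the varimax and
   promax parts so it maps the unrotated loadings directly. Scores and
   loadings are both multiplied by the rotation matrix. Factor signs are
   fixed so each factor's largest-|loading| gene is positive, and rotated
   factors are ordered by score variance — both pure presentation
   conventions needed for determinism.

## Factor–covariate association (FCA)

For each level of each categorical covariate a one-vs-rest label vector is
scored by four classifiers on the factor scores: logistic regression
(importance = |coefficient|), decision tree and XGBoost (impurity-decrease
importances, library defaults, fixed seed), and a linear threshold
classifier whose importance is the ROC AUC obtained from the Mann–Whitney
U statistic (AUC = U/(n₀n₁)), rectified to max(AUC, 1 − AUC) because factor
signs are arbitrary. Each classifier's k-vector is scaled across factors —
standardization (default), min–max, or rank r_i/n — and the scaled vectors
are combined by arithmetic (default) or geometric mean. The geometric mean
is refused under standardization (log of non-positive values); with
min–max/rank scaling a 1e-12 offset guards exact zeros. Numeric covariates
are not scored by classifiers; they are handled by direct Pearson
correlation with factor scores (`factor_covariate_correlation`, flagging
|r| > 0.45 as technically driven).

Significance calls binarize the pooled FCA values (all covariates together,
one distribution) at the Otsu threshold: an exhaustive scan over midpoints
of consecutive sorted unique values maximizing the between-class variance
w₀w₁(m₀ − m₁)². Constant input has no threshold and raises.

## Permutation calibration and Gini

Shuffling a covariate's labels B times (default 500; 200 for the
desk-scale benchmark) and re-running the full ensemble per shuffle yields
an empirical null per (level, factor) cell; p = #(perm ≥ obs)/B exactly,
with an optional (r+1)/(B+1) smoothed variant and an optional pooled-null
(across factors within a level) variant. No multiple-testing correction is
applied; the expectation under a well-calibrated pipeline is one
significant association (p < 0.05) per covariate level. Association
sparsity is summarized by the Gini coefficient of each level's scores
across factors, G_k = ΣΣ|x_i − x_j| / (2n²x̄) (computed by the O(n log n)
sorted identity), averaged over levels into a global index. Standardized
FCA scores can be negative, so the table is shifted by its global minimum
first; G_k is scale-invariant and decreases when a constant is added, as
an inequality measure should.

## Interpretability metrics (FIS)

Separability (label-free, on a 2-means split of each factor's scores,
best of 10 restarts): silhouette; variance-ratio score VRS = BSS/WSS (raw
sum-of-squares ratio, no (n−k)/(k−1) factor — the Calinski–Harabasz
normalized variant is an option); WVRS = squared mean gap over the
unweighted mean of the two cluster variances (cluster-size free; a
per-cluster-SS-average variant sits behind a flag); Davies–Bouldin mapped
to (0, 1] by 1/(1 + DBI) so higher is better; the bimodality index of a
tied-variance two-component Gaussian mixture, BI = π(1 − π)·δ with
δ = |μ₁ − μ₂|/σ (the classical √(π(1−π))·δ variant is available via
`sqrt_proportions=True`; the plain-product form is the default on
purpose); and Hartigan's dip statistic, implemented in-package via the
classical greatest-convex-minorant / least-concave-majorant algorithm
(statistic only, no p-value). Effect size is the score variance.
Specificity applies Simpson (D = Σp_i², 1 = specific) and Shannon
(H = −Σp_i log p_i) diversity to a factor's FCA column, rectified at zero
and normalized to probabilities; Shannon is presented as
(log N − H)/log N so that, like Simpson, higher means more specific.
Homogeneity is the scaled variance SV = Var(x_L)/Var(x) per covariate
level, averaged arithmetically over levels (ASV; geometric mean
available). The default FIS rows are silhouette, bimodality index,
variance, Simpson, and one arithmetic-ASV row per categorical covariate —
the metrics the simulation study selects; the rest are computed with
`all_metrics=True`. The presentation copy is row-wise min–max scaled.

## Mixture simulation and overlap

Synthetic factors are drawn from p·N(μ₁, σ₁²) + (1 − p)·N(μ₂, σ₂²) with
p = 0.5, μ ~ U(0, 4), σ ~ U(0.5, 1) per factor. Ground-truth difficulty is
the component overlap

    O = 1 − ½[erf((c − μ₁)/(√2σ₁)) − erf((c − μ₂)/(√2σ₂))],  μ₁ < μ₂,

at the density intersection c (midpoint for equal σ; for unequal σ the
quadratic root between the means — the single-intersection formula is
exact in the equal-σ regime, and deviations from the numerical-integration
oracle are reported by the tests, not hidden). Correlating each metric
with O across factors, per round, gives the validation: separability
metrics should correlate negatively, homogeneity (ASV, computed with the
true component labels as a 2-level covariate) positively. Specificity
requires an association score per factor; it is wired by running the
ensemble FCA with each factor's own component labels as the covariate — a
documented convention. Reference scale is 10 000 cells × 10 factors × 100
rounds; the test suite and acceptance run use 1000 × 10 × 20, which
reproduces the sign structure with tight round-to-round spread.

## Synthetic benchmark fixture

`make_fixture_dataset` emulates a mixture-of-cell-lines design: 3 lines ×
3 protocols × 50 cells (450 cells), 300 genes. Counts are
Poisson(s_i · b_j · e_ij) with log-normal gene baselines (log-sd 1),
protocol depth scales (0.6, 1.0, 1.6) with per-cell log-normal jitter
(log-sd 0.15), and disjoint 20-gene line programs at 3-fold effect whose
per-cell activity is log-normal (log-sd 0.6). The activity spread matters:
with pure mean-shift programs the three centered line patterns span an
exactly rank-2 subspace (the centered indicators of 3 balanced groups sum
to zero) and no rotation can produce three one-to-one line factors;
cell-to-cell program-intensity variation — a ubiquitous property of real
expression programs — gives each line its own variance axis, making the
line signal rank 3 and cleanly identifiable. What the fixture does not
emulate: overdispersion beyond Poisson, dropout beyond sampling zeros,
gene–gene correlation within programs, ambient contamination, or doublets;
passing on it shows the pipeline recovers planted, well-separated
structure at small scale, not performance on real atlases.

## Numerical and design choices

- Design encoding: intercept always present; categoricals one-hot with the
  lexicographically first level as reference; numerics standardized;
  collinear columns dropped by a rank-revealing scan with a warning.
  Library size enters as log total counts (log link).
- Score-equation check: response residuals are orthogonal to every design
  column for converged fits (Σ x_ij(y_i − μ̂_i) = 0); the Pearson analogue
  holds only for intercept-only fits, where μ̂ is constant.
- Cross-residual-type robustness is judged after matching factors between
  factorizations by absolute score correlation (Hungarian assignment),
  since factor indices are arbitrary presentation order.
- Empirical p-values of 0 are printed as "< 1/B" in text output.
- Otsu on constant input, ASV on zero-variance factors, k-means on
  constant scores, and Simpson on all-non-positive columns raise rather
  than return a placeholder.
- Problem sizes in the shipped tests (450 × 300 fixture, k = 10, 200
  permutations; 1000-cell simulation, 20 rounds) are chosen as the
  smallest at which the planted structure is unambiguous; all defaults
  scale up unchanged.

## Known limitations

- Strict Poisson: no overdispersion or negative-binomial option.
- Oblique (promax) scores follow the multiply-by-rotation convention, so
  score · loadingᵀ reconstruction invariance holds only for orthogonal
  rotations.
- The unequal-σ overlap formula uses one density intersection; for very
  unequal spreads with two relevant intersections it is an approximation.
- KNN and random-forest importances are deliberately absent from the
  ensemble (poor accuracy / scalability respectively).
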