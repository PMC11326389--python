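# scired

Interpretable factor discovery for single-cell RNA-seq count data.

Matrix factorizations of expression data produce axes of variation, but not
their meaning: which factor is a batch effect, which is a cell-type
program, which tracks sex or stimulation? `scired` makes factors
interpretable in three moves:

1. **Residualize.** Every gene is fitted by a Poisson GLM (log link) on the
   known technical covariates — library size, protocol, batch — and the
   Pearson residuals `(y − μ̂)/√μ̂` carry forward only the unexplained
   structure.
2. **Factorize and rotate.** The residual matrix is decomposed by
   SVD-based PCA and the top-k loadings are varimax-rotated (promax
   available) so each factor concentrates on few genes.
3. **Associate and evaluate.** Each factor is matched to covariate levels
   by an ensemble of classifiers — logistic regression, decision tree,
   XGBoost, and a Mann–Whitney/AUC linear classifier — whose scaled
   importances average into a factor–covariate association (FCA) table,
   binarized at an Otsu threshold. A factor-interpretability score (FIS)
   table adds label-free separability (silhouette, bimodality index, dip,
   variance-ratio scores), effect size (variance), specificity (Simpson /
   Shannon of a factor's FCA column) and homogeneity (average scaled
   variance across covariate levels).

Calibration tooling is built in: a label-permutation benchmark (empirical
p-values per covariate level × factor, Gini sparsity summaries) and a
two-component Gaussian-mixture factor simulator with analytic component
overlap `O = 1 − ½[erf((c−μ₁)/√2σ₁) − erf((c−μ₂)/√2σ₂)]` for validating
that the interpretability metrics track separability.

It is aimed at analysts of single-cell (or bulk) count matrices who want
factor models they can annotate, audit and trust, rather than embeddings.

## Worked example

On a synthetic benchmark of 3 cell lines × 3 library protocols (450 cells,
300 genes; each line carries a disjoint 3-fold 20-gene program, each
protocol a different sequencing depth):

```python
import scired as sr

counts, cov = sr.make_fixture_dataset(sr.FixtureConfig(seed=11))
design = sr.build_design_matrix(cov, ["protocol", "library_size"])
resid  = sr.compute_residual_matrix(counts, design, "pearson")
model  = sr.RotatedFactorizer(n_factors=10, rotation="varimax").fit(resid).model_
fca    = sr.ensemble_fca(model, cov, ["line"], seed=0)
calls  = sr.call_associations(fca)
print(fca.values.round(2).iloc[:, :5])
print(calls.matched_factors)
```

```
              F1    F2    F3    F4    F5
line:line1  2.40  0.64  0.48 -0.51 -0.36
line:line2  0.10  0.13  2.87 -0.42 -0.41
line:line3  0.37  2.65  0.39 -0.39 -0.37
{'line:line1': ['F1'], 'line:line2': ['F3'], 'line:line3': ['F2']}
```

Each line level associates with exactly one distinct factor (one-to-one):
the ensemble scores are standardized importances averaged over the four
classifiers, and the Otsu threshold (1.52 here) separates the three
planted associations from the background. The FIS table shows why these
factors are the interpretable ones — high separability and effect size,
low homogeneity across line levels:

```python
fis = sr.build_fis_table(model, fca, cov, seed=0)
print(fis.values.round(3).iloc[:, :5])
```

```
                              F1      F2      F3     F4     F5
silhouette                 0.681   0.721   0.730  0.549  0.532
bimodality_index           0.536   0.557   0.291  0.410  0.338
variance                  30.856  28.996  24.530  3.118  3.099
simpson                    0.715   0.634   0.617  0.333  0.333
asv_arithmetic[line]       0.360   0.334   0.437  0.992  0.985
asv_arithmetic[protocol]   1.000   1.000   1.000  1.000  1.000
```

A factor specific to one line keeps little of its variance within each
line level (ASV ≈ 0.3–0.4) while noise factors are homogeneous (ASV ≈ 1);
Simpson 0.33 = 1/3 is the uniform floor over three levels. Ranked gene
lists per factor (`sr.top_genes(model, "F1", n=200)`) feed external
enrichment tools; `sr.factor_covariate_correlation` flags factors that
merely track numeric technical covariates (|r| > 0.45).

The same pipeline is scriptable from a shell:

```sh
scired fixture --out data/ --seed 11
scired residuals --counts data/counts.csv --covariates data/covariates.csv \
       --regress protocol,library_size --out residuals.csv
scired factorize --residuals residuals.csv --k 10 --out model/
scired fca --model model/ --covariates data/covariates.csv --levels line --out fca/
```

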