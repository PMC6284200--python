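# dpseq

Differential gene-expression testing for RNA-seq count data under a
**double-Poisson (DP) model**, paired with a negative-binomial (NB) model,
a five-stage empirical-Bayes dispersion cascade, and a Wald test.

## Why

RNA-seq counts are usually modelled as negative binomial, which covers
equidispersion (variance = mean) and overdispersion (variance > mean) but
cannot represent **underdispersion** (variance < mean), a pattern that a
sizeable fraction of genes in real count matrices shows, especially at low
read counts and high coverage. The NB analysis of such genes is forced to
a floored dispersion and becomes conservative. Efron's double-Poisson
family covers all three regimes with two parameters:

    E(Y) = mu,    Var(Y) = mu / theta

with `theta > 1` underdispersed, `theta = 1` Poisson, `0 < theta < 1`
overdispersed. `dpseq` fits both families and offers three modes:

- **dp** — DP family only,
- **nb** — NB family only (`Var = mu + mu^2 * phi`),
- **mix** — both; each gene's p-value is the smaller of the two, taken
  before FDR adjustment.

Per family, gene dispersions are estimated in five stages: method-of-moments
initialiser → gene-wise maximum likelihood (Cox–Reid adjusted) → a lowess
mean-dispersion trend → maximum-a-posteriori shrinkage under a log-normal
prior fitted from all genes → a "window scan" that walks genes by mean and
replaces each dispersion by the max (NB) or min (DP) of its own value and
its window-type median. Testing is a Wald statistic

    W = |mu_1 - mu_2| / sqrt(s_1^2 + s_2^2)

with group variances from the family's mean-variance law at the final
dispersion (per-group variance of the mean by default), two-sided normal
p-values, Benjamini–Hochberg adjustment, and the DEG rule
`padj < 0.05 AND (FC < 0.67 OR FC > 1.5)`.

The package also ships the DP-based simulator used to benchmark the method
(counts drawn from the exact DP density; known DE labels) and an evaluation
harness (FPR/TPR, ROC/AUC, precision-recall, DEG counts, optionally
stratified by observed dispersion class) that also scores result tables
from external tools.

## Worked example

```python
from dpseq import DEModel
from dpseq.simulate import synth_params, simulate_dataset

params = synth_params(5000, seed=42)             # per-gene (mu, theta)
ds, truth = simulate_dataset(params, n_de=1000, seed=42)
res = DEModel(ds, mode="mix").fit()
print(res.summary())
```

```
Two-group differential expression
====================================================
mode:                 MIX
normalization:        tmm
samples:              6 (group1 vs group2)
genes analyzed:       4998
genes filtered (0):   2
underdispersed:       2932 (58.7%)
DP prior:             m0=0.1984, tau=1.0249
NB prior:             m0=-5.1071, tau=2.1109
DEGs (padj<0.05, FC): 865
min padj:             0
====================================================
```

Two all-zero genes were filtered before analysis; 58.7% of genes have a
pooled within-group variance below their mean (underdispersed); the two
log-normal priors are the fitted shrinkage hyperparameters (centre `m0`,
width `tau`, log scale); 865 genes pass the combined significance + fold
change rule, recovering 83% of the 1,000 truly DE genes in this run.
`res.frame` holds the per-gene table (group means, fold change, Wald `W`,
per-family and combined p-values, `padj`, DEG flag, dispersion class), and
`res.dispersions["dp"].frame` the five dispersion stages per gene.

The same pipeline runs from the shell:

```sh
dpseq simulate --n-genes 5000 --n-de 1000 --seed 42 \
      --out-counts sim.tsv --out-truth truth.tsv
dpseq test sim.tsv --groups g1,g1,g1,g2,g2,g2 --mode mix --out results.tsv
dpseq evaluate --truth truth.tsv --counts sim.tsv \
      --results dpseq=results.tsv --out metrics.tsv
```

Counts are plain delimited text (genes as rows, first column gene IDs,
header of sample IDs; tab or comma). `dpseq normalize` and
`dpseq dispersion` expose the intermediate size factors and the dispersion
table; every command writes a JSON manifest with its full configuration.

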