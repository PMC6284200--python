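# Methods

## Count models

Let `Y_ijk` be the read count of gene `i` in replicate `j` of group `k`
(`K = 2` groups, `J >= 2` replicates each, `n = KJ`). Two families are
fitted per gene:

**Negative binomial.** Mean `mu`, dispersion `phi >= 0`,
`Var = mu + mu^2 phi`. `phi = 0` is the Poisson; the family cannot
represent variance below the mean. Likelihood work treats
`phi <= 1e-10` as exactly Poisson (the Gamma(1/phi) terms lose more
precision than the limit does).

**Double Poisson.** Efron's exponential-dispersion extension with mean
`mu` and dispersion `theta > 0`, `Var = mu / theta`. The closed-form
density

    f(y) = sqrt(theta) e^{-theta mu} (e^{-y} y^y / y!) (e mu / y)^{theta y}

(singular factors at `y = 0` read as 1, so `f(0) = sqrt(theta)
e^{-theta mu}`) sums to `1/c(mu, theta)` rather than 1; the exact pmf
multiplies by `c`. `c` is computed two ways: the closed form
`1/c = 1 + (1-theta)/(12 mu theta) (1 + 1/(mu theta))`, and truncated
summation over `0..max(50, mu + 20 sqrt(mu/theta))`, a support that
carries all but < 1e-10 of the mass for every regime we use. The closed
form is a continuous expansion: it is accurate to well under 1% whenever
`mu theta >= 2` **and** the distribution is wider than the integer
lattice (`sd = sqrt(mu/theta)` of order 1 or more); in the extreme
underdispersed corner (e.g. `mu = 2, theta = 20`, sd 0.32) the mass
collapses onto single integers and only the summation form is valid.
All pmf evaluation is in log space via `gammaln`.

The sampler draws from the **exact** density by inverse CDF over the
truncated support, so simulated data follow a proper probability
distribution; the estimation stages use the closed-form density, whose
`theta`-derivative is the estimating equation written by the method
(including the `theta`-dependence of `c` was tried and slightly worsens
calibration; it is not used).

## Normalization

Counts are scaled by per-sample size factors; TMM is the default with
total-count, upper-quartile, median and median-of-ratios ("deseq")
alternatives. The TMM implementation follows the canonical defaults:
reference = library whose upper quartile of depth-scaled counts is
closest to the mean; genes with a zero in either library excluded;
log-ratio trim 30%, abundance trim 5% (rank-based); weights =
inverse asymptotic variance of the log-ratio; factor applied to library
size. All methods are anchored so the geometric mean of the size factors
is 1 (verified to 1e-12). The implementation reproduces edgeR 4.0.16's
`calcNormFactors(method="TMM")` to 1e-6 on a fixture (frozen in the test
suite). If every gene of a sample is trimmed away the sample falls back
to total-count scaling with a logged warning.

## Dispersion cascade

Estimating a per-gene dispersion from `n = 6` observations is hopeless
without sharing information; the cascade stabilises the estimates in
five stages, run separately per family. Dispersions are assumed equal
between groups, so all `n` samples contribute.

1. **Moments.** Pooled mean `mu_i = xbar_i * sbar` (normalized all-sample
   mean scaled back by the average size factor) and pooled variance
   `sigma2_i = sbar^2 *` (df-weighted within-group variance of normalized
   counts), so a real group difference does not masquerade as dispersion.
   `phi_init = (sigma2 - mu)/mu^2`, floored at 1e-8 when `sigma2 < mu`
   (the NB family cannot fit underdispersion; the floor deliberately
   overestimates the variance and yields a conservative NB test there);
   `theta_init = mu/sigma2`, clipped to [1e-4, 1e4]. Genes with zero
   counts everywhere are removed before the cascade.

2. **Gene-wise likelihood.** One-dimensional maximisation over
   log-dispersion at fixed fitted means `mu_ijk = xbar_ik * s_jk` (each
   observation keeps its own depth), bounds `phi` in [1e-8, 1e4], `theta`
   in [1e-4, 1e4]. The objective is the family log-likelihood with the
   **Cox–Reid adjustment** `-(1/2) sum_k log(sum_j w_jk)` (`w` the GLM
   working weight: `mu theta` for DP, `mu/(1+phi mu)` for NB),
   compensating for the group means being estimated from the same
   counts; without it the dispersion-driven variance is under-used by a
   factor `n/(n-K)` (measured: +0.54 median log-bias on DP `theta` at
   `J = 3`, and a null false-positive rate of 0.13 instead of ~0.07).
   Samples whose fitted mean is zero are deterministic zeros and are
   excluded; groups with zero mean carry no adjustment term.

   *Optimiser.* A 41-point log-grid locates the best bracket and ~45
   golden-section iterations refine it, vectorised across all genes
   (the DP objective is concave in log-theta, so this is exact; the NB
   objective is well-behaved in practice). The returned value is never
   worse than the initialiser — evaluating both and keeping the better
   one subsumes the non-convergence fallback. Grid + refinement resolve
   the optimum to ~1e-8 in log units.

3. **Common trend.** Lowess (span 0.3, 3 robustness iterations) of log
   gene-wise dispersion on log mean, evaluated at every gene and clipped
   to the family bounds. Gene-wise estimates sitting at the bounds are
   numerical sentinels, not data — with many underdispersed genes the
   NB floor would otherwise drag the trend (and the prior centre below)
   to log(1e-8) and destroy the NB test's calibration for overdispersed
   genes — so the trend is fitted on interior estimates only and
   interpolated to all genes. Fewer than 50 usable genes: median
   fallback, logged.

4. **Shrinkage.** Gene-wise dispersions are modelled as log-normal:
   centre `m0 = median(log common)`, width `tau = 1.4826 * MAD(log
   genewise - log common)` floored at 0.25 (both over interior genes;
   the floor prevents a degenerate point-mass prior). Each gene is
   re-estimated by MAP: the CR-adjusted log-likelihood plus
   `log N(log disp; m0, tau^2)` — the log-normal prior in its log
   parameterisation, which leaves the estimate untouched in the flat
   prior limit.

5. **Window scan.** Genes are ranked by pooled mean (ties broken by gene
   ID so the result is order-invariant) and cut into windows of width 1
   normalized count; windows under 20 genes are merged with the next
   (trailing remainder backward). Within a window, genes with shrunk
   dispersion at or above the trend are I-type, below it II-type; the
   final dispersion is `max(own, type median)` for NB and `min(own,
   type median)` for DP. Both rules push toward *larger* variance
   (NB variance grows with `phi`, DP variance grows as `theta` falls),
   guarding the test against variance underestimation by individual
   noisy genes. The window width and minimum occupancy are
   configurable; occupancy keeps type medians stable.

## Testing

`W = |mu_1 - mu_2| / sqrt(s_1^2 + s_2^2)` with `s_k^2` the family
variance at the group mean under the final dispersion, divided by the
group's replicate number (the variance of the estimated mean). The
undivided model variance is available via `variance_of_mean=False`; it
makes every test more conservative by roughly `sqrt(J)` and is kept as
an option only. Degenerate cases: both variances zero and equal means
give `W = 0, p = 1`; unequal means give `W = inf, p = 0`. P-values are
two-sided standard normal, adjusted by Benjamini–Hochberg (delegated to
statsmodels; verified against a brute-force step-up oracle). In mix
mode the per-gene p-value is `min(p_DP, p_NB)` and BH is applied after
the minimum — slightly anti-conservative by construction, accepted as
the design of the combined mode. Fold change is the ratio of normalized
group means (group2/group1, first condition level = control; 0/0 reads
as 1, x/0 as infinity, counted as upregulated); the DEG rule is strict:
`padj < alpha` and `FC < 0.67` or `FC > 1.5`.

## Simulator

`synth_params` draws `mu` log-uniform on [1, 1e4] and `log theta ~
N(0, 0.7)` truncated to the DP bounds — moderately deep two-group bulk
experiments with an even split of under- and overdispersed genes.
`estimate_sim_params` instead estimates `(mu, theta)` from a real count
matrix (pooled mean + DP gene-wise MLE). `simulate_dataset` picks the DE
genes and their effects on one RNG stream and draws counts on another,
so truth labels are stable across re-draws; DE genes multiply the
group-2 mean by a fold change with `|log2 FC|` uniform on [0.585, 2]
(1.5x–4x, spanning upward from the DEG threshold) and random sign;
`theta` is shared between groups, matching the estimation assumption;
all simulated size factors are 1 (depth variation is the normaliser's
job). The reference design is 10,000 genes, 2,000 DE, two groups of
three.

What the simulator does *not* emulate: library-size and composition
effects, gene-gene correlation, zero inflation and single-cell
bimodality, positional/coverage bias, and any mean-dispersion coupling
(`theta` is drawn independently of `mu`). Passing tests therefore
demonstrate correctness of the machinery and calibration under the
stated generative law, not performance on any particular real dataset.
The independence of `theta` and `mu` matters: it makes the lowess trend
uninformative, so the shrinkage stages cannot reduce per-gene noise as
much as they can on real data, where dispersion tracks expression
strength. Under this generator the DP-mode null type-I error at the
0.05 level is ~0.07 (the Wald test with the *true* dispersions gives
0.048; the excess is dispersion-estimation noise and the small-sample
median bias of the deviance estimator at `n - K = 4` df), and the mix
mode adds the anti-conservativeness of the per-gene minimum, landing
near 0.08.

## Evaluation harness

FPR = fraction of truly non-DE genes with `p < alpha`; TPR = the same
over DE genes (raw p by default; DEG counts use adjusted p). Empty
strata report missing, not zero. ROC/AUC and precision-recall rank by
ascending p; AUC is the rank-based (Mann–Whitney, ties count half)
area, delegated to scikit-learn and verified against a pairwise-count
oracle. The PR curve reports the efficient frontier of the threshold
sweep — the best precision at each achievable recall — anchored at
recall 0 with the top tie-group's precision. External methods are
scored from delimited tables with `gene_id` and `pvalue` columns; genes
a method omits count as `p = 1` (logged). Stratified reporting
classifies genes on the observed counts (pooled `sigma2 < mu` =
underdispersed, ties non-underdispersed), since that is all one can
observe on real data; the generating `theta` remains available in the
truth table for oracle stratification.

## Numerical choices and limitations

- All randomness flows through explicit seeds; the analysis path is
  deterministic and invariant to gene order (verified).
- Dispersion bounds [1e-8, 1e4] (NB) and [1e-4, 1e4] (DP); boundary
  hits are legitimate outputs (constant genes cap DP `theta`).
- Problem sizes in the test and acceptance runs (2,000-gene null
  datasets, 10 replicates; 2,700-gene power grids, 5 replicates) keep
  full-cascade runs to seconds while leaving Monte-Carlo error well
  below the asserted margins.
- Two-group designs only; no covariates, no multi-factor models, no
  per-group dispersions.
- The mix mode's minimum-p construction has no multiplicity correction
  at the per-gene level; its type-I error is above each component's by
  design.
- The DP mean is `E(Y) ~= mu` only to the accuracy of the Efron
  expansion; at very small `mu theta` the realised mean of the exact
  density drifts from the nominal `mu`. Estimation is unaffected (means
  are estimated from data), but parameter-recovery comparisons at
  `mu theta < 1` should expect this.
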