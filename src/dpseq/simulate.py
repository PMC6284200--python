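"""Double-Poisson count simulator and the underdispersion classifier.

Benchmarking a differential-expression method needs datasets whose true
DE status is known.  The simulator draws every count from the exact DP
density with a per-gene (mean, dispersion) parameterisation obtained
either from a real count matrix (:func:`estimate_sim_params`) or
synthetically (:func:`synth_params`).  The reference design mirrors a
typical small-sample two-group experiment: 10,000 genes of which 2,000
are differentially expressed, two groups, three replicates each, with
the dispersion shared between groups and all size factors equal to one
(depth variation is the normaliser's job, not the simulator's).

DE genes get their group-2 mean multiplied by a fold change with
``|log2 FC|`` uniform on [0.585, 2] (1.5x to 4x, spanning upward from
the DEG-calling threshold) and random sign.  Truth labels and effects
use a separate RNG stream from the count draws, so the labelling is
stable under re-draws with the same seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import CountDataset
from .dispersion import genewise_mle, initial_dispersion, pooled_moments
from .families import DP_THETA_MAX, DP_THETA_MIN, dp_sample
from .normalize import SizeFactors, compute_size_factors, normalize_counts

__all__ = [
    "estimate_sim_params",
    "synth_params",
    "simulate_dataset",
    "classify_dispersion",
    "SimTruth",
]


class SimTruth:
    """Ground truth of a simulated dataset.

    ``frame`` columns: gene_id index, mu (baseline mean), theta, fc
    (1 for non-DE genes), is_de.  Also carries the global design:
    seed, n_genes, n_de, J (replicates per group), K (=2 groups).
    """

    def __init__(self, frame: pd.DataFrame, seed, n_reps, n_groups=2):
        self.frame = frame
        self.seed = seed
        self.J = n_reps
        self.K = n_groups

    @property
    def is_de(self):
        return self.frame["is_de"]

    @property
    def n_de(self):
        return int(self.frame["is_de"].sum())

    def to_csv(self, path, sep="\t"):
        out = self.frame.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep=sep, index=False, float_format="%.6g")


def estimate_sim_params(dataset: CountDataset, normalization="tmm") -> pd.DataFrame:
    """Per-gene (mu, theta) estimated from a real count matrix.

    mu is the pooled normalized mean, theta the DP gene-wise MLE at the
    fitted group means; all-zero genes are dropped.
    """
    data, _ = dataset.drop_all_zero_genes()
    sf = compute_size_factors(data, normalization)
    mu, sigma2 = pooled_moments(data, sf)
    init = initial_dispersion(mu, sigma2, "dp")
    from .dispersion import group_means

    _, mu_ijk = group_means(data, sf)
    theta = genewise_mle(data.counts.to_numpy().astype(float), mu_ijk, init, "dp")
    return pd.DataFrame({"mu": mu, "theta": theta}, index=data.gene_ids)


def synth_params(n_genes, seed, mu_log_range=(1.0, 1e4), theta_log_sd=0.7) -> pd.DataFrame:
    """Synthetic per-gene (mu, theta) table.

    mu is log-uniform over ``mu_log_range``; log theta is
    Normal(0, theta_log_sd), truncated to the DP bounds, which yields a
    roughly even split of under- (theta > 1) and overdispersed genes.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = mu_log_range
    if not (0 < lo < hi):
        raise ValueError("mu_log_range must be increasing and positive")
    if theta_log_sd < 0:
        raise ValueError("theta_log_sd must be non-negative")
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), n_genes))
    theta = np.exp(rng.normal(0.0, theta_log_sd, n_genes)) if theta_log_sd > 0 else np.ones(n_genes)
    theta = np.clip(theta, DP_THETA_MIN, DP_THETA_MAX)
    ids = [f"g{i+1}" for i in range(n_genes)]
    return pd.DataFrame({"mu": mu, "theta": theta}, index=ids)


def simulate_dataset(params: pd.DataFrame, n_de, seed, n_reps=3,
                     fc_log2_range=(0.585, 2.0)):
    """Simulate a two-group count dataset from per-gene DP parameters.

    Parameters
    ----------
    params : DataFrame with columns mu, theta (gene IDs as index).
    n_de : int
        Number of DE genes (0 gives a pure null dataset).
    seed : int
        Master seed; truth assignment and count draws use independent
        child streams, so truth labels do not depend on the draws.
    n_reps : int
        Replicates per group (J); groups are fixed at K=2.
    fc_log2_range : (float, float)
        ``|log2 FC|`` of DE genes is uniform over this range, sign random.

    Returns
    -------
    (CountDataset, SimTruth)
    """
    n_genes = len(params)
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed the number of genes")
    ss = np.random.SeedSequence(seed)
    truth_rng, count_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    mu = params["mu"].to_numpy(dtype=float)
    theta = params["theta"].to_numpy(dtype=float)
    fc = np.ones(n_genes)
    is_de = np.zeros(n_genes, dtype=bool)
    if n_de > 0:
        de_idx = truth_rng.choice(n_genes, size=n_de, replace=False)
        lo, hi = fc_log2_range
        mag = truth_rng.uniform(lo, hi, n_de)
        sign = truth_rng.choice([-1.0, 1.0], n_de)
        fc[de_idx] = 2.0 ** (sign * mag)
        is_de[de_idx] = True

    counts = np.empty((n_genes, 2 * n_reps), dtype=np.int64)
    for i in range(n_genes):
        if fc[i] == 1.0:  # same marginal in both groups: one pmf build
            counts[i] = dp_sample(mu[i], theta[i], 2 * n_reps, count_rng)
        else:
            counts[i, :n_reps] = dp_sample(mu[i], theta[i], n_reps, count_rng)
            counts[i, n_reps:] = dp_sample(mu[i] * fc[i], theta[i], n_reps, count_rng)

    condition = ["group1"] * n_reps + ["group2"] * n_reps
    samples = [f"group1_r{j+1}" for j in range(n_reps)] + [
        f"group2_r{j+1}" for j in range(n_reps)]
    dataset = CountDataset(counts, condition=condition,
                           gene_ids=list(params.index), sample_ids=samples)
    truth = SimTruth(
        pd.DataFrame({"mu": mu, "theta": theta, "fc": fc, "is_de": is_de},
                     index=params.index),
        seed=seed, n_reps=n_reps)
    return dataset, truth


def classify_dispersion(dataset: CountDataset, size_factors: SizeFactors = None) -> pd.Series:
    """Classify each gene by its pooled moments against the unit line.

    ``sigma2 < mu`` is underdispersed; on or above the line (including
    the tie sigma2 == mu) is non-underdispersed.  When the dataset has
    no condition factor the variance pools all samples as one group.
    """
    if size_factors is None:
        size_factors = compute_size_factors(dataset, "tmm")
    if dataset.condition is not None:
        mu, sigma2 = pooled_moments(dataset, size_factors)
    else:
        x = normalize_counts(dataset, size_factors).to_numpy()
        s = size_factors.to_numpy()
        sbar = s.mean()
        mu = x.mean(axis=1) * sbar
        sigma2 = sbar**2 * x.var(axis=1, ddof=1)
    label = np.where(sigma2 < mu, "underdispersed", "non-underdispersed")
    return pd.Series(label, index=dataset.gene_ids, name="dispersion_class")
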