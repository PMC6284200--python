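"""Size-factor estimation and count normalization.

Sequencing depth and library composition differ between samples, so raw
counts are divided by a per-sample size factor before any comparison.
The default is TMM (trimmed mean of M-values): log-ratios of each sample
against a reference library are trimmed (30% on M, 5% on A), averaged
with inverse-asymptotic-variance weights, and turned into a scale for
the library size.  Total-count, upper-quartile, median and
median-of-ratios ("deseq") factors are available as alternatives.  All
methods rescale so the geometric mean of the size factors is one.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datasets import CountDataset

__all__ = ["SizeFactors", "compute_size_factors", "normalize_counts"]

logger = logging.getLogger(__name__)

METHODS = ("tmm", "total", "upper_quartile", "median", "deseq")


class SizeFactors:
    """Per-sample positive scale factors with the method that made them."""

    def __init__(self, s, method, sample_ids=None):
        s = pd.Series(np.asarray(s, dtype=float),
                      index=sample_ids if sample_ids is not None else None)
        if np.any(s.to_numpy() <= 0) or not np.all(np.isfinite(s.to_numpy())):
            raise ValueError("size factors must be positive and finite")
        self.s = s
        self.method = method

    def __len__(self):
        return len(self.s)

    def to_numpy(self):
        return self.s.to_numpy()

    def __repr__(self):
        return f"<SizeFactors method={self.method} n={len(self)}>"


def _geomean_one(s):
    return s / np.exp(np.mean(np.log(s)))


def _tmm_factor(obs, ref, n_obs, n_ref, logratio_trim=0.30, abs_trim=0.05):
    """edgeR-style TMM log2 factor of one library against the reference."""
    both = (obs > 0) & (ref > 0)
    if not np.any(both):
        return np.nan
    p_obs = obs[both] / n_obs
    p_ref = ref[both] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M
    w = (n_obs - obs[both]) / (n_obs * obs[both]) + (n_ref - ref[both]) / (n_ref * ref[both])
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep) or w[keep].sum() == 0:
        return np.nan
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def compute_size_factors(dataset: CountDataset, method: str = "tmm") -> SizeFactors:
    """Estimate per-sample size factors; geometric mean anchored at 1.

    ``method`` is one of ``tmm`` (default), ``total``, ``upper_quartile``,
    ``median``, ``deseq``.  A sample with all-zero counts is an error.
    """
    if method not in METHODS:
        raise ValueError(f"unknown normalization method {method!r}; choose from {METHODS}")
    y = dataset.counts.to_numpy().astype(float)
    lib = y.sum(axis=0)
    if np.any(lib == 0):
        bad = dataset.sample_ids[lib == 0].tolist()
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    n_samp = y.shape[1]
    if n_samp == 1:
        return SizeFactors([1.0], method, dataset.sample_ids)

    if method == "total":
        s = lib.copy()
    elif method == "upper_quartile":
        s = np.array([np.quantile(col[col > 0], 0.75) for col in y.T])
    elif method == "median":
        s = np.array([np.median(col[col > 0]) for col in y.T])
    elif method == "deseq":
        allpos = np.all(y > 0, axis=1)
        if not np.any(allpos):
            raise ValueError("deseq normalization needs at least one gene with all-positive counts")
        logg = np.log(y[allpos])
        logref = logg.mean(axis=1, keepdims=True)
        s = np.exp(np.median(logg - logref, axis=0))
    else:  # tmm
        # reference library: upper quartile of depth-scaled counts closest to the mean
        f75 = np.array([np.quantile(col / N, 0.75) for col, N in zip(y.T, lib)])
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
        ref = y[:, ref_idx]
        log2f = np.zeros(n_samp)
        for j in range(n_samp):
            if j == ref_idx:
                continue
            fj = _tmm_factor(y[:, j], ref, lib[j], lib[ref_idx])
            if not np.isfinite(fj):
                logger.warning(
                    "TMM: no genes survived trimming for sample %s; "
                    "falling back to total-count scaling", dataset.sample_ids[j])
                fj = 0.0
            log2f[j] = fj
        s = lib * 2.0 ** log2f

    s = _geomean_one(np.asarray(s, dtype=float))
    logger.info("size factors (%s): %s", method,
                np.array2string(s, precision=4, separator=", "))
    return SizeFactors(s, method, dataset.sample_ids)


def normalize_counts(dataset: CountDataset, size_factors: SizeFactors) -> pd.DataFrame:
    """Normalized counts: entry (i, j) = Y_ij / s_j."""
    s = size_factors.to_numpy()
    if len(s) != dataset.n_samples:
        raise ValueError("size-factor length does not match number of samples")
    if np.any(s <= 0):
        raise ValueError("size factors must be positive")
    return dataset.counts / s
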