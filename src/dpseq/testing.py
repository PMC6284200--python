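"""Wald test, multiple-testing adjustment and DEG calling.

The null hypothesis per gene is equality of the two group means.  The
Wald statistic is

    W = |mu_1 - mu_2| / sqrt(se_1^2 + se_2^2)

where each group's variance comes from the family's mean-variance law at
the group mean using the *final* dispersion (NB: mu + mu^2 phi; DP:
mu / theta).  By default each group variance is divided by its replicate
number (the variance of the estimated mean, as in the Wald tests of DSS
and DESeq2); ``variance_of_mean=False`` uses the raw model variance.
Two-sided p-values come from the standard normal reference; BH controls
the FDR.  A gene is called differentially expressed when its adjusted
p-value is below ``alpha`` *and* its fold change lies outside
``[fc_low, fc_high]`` (defaults 0.67 and 1.5).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "wald_statistic",
    "wald_pvalue",
    "bh_adjust",
    "fold_change",
    "call_degs",
    "group_variances",
]


def group_variances(mu_ik, disp_final, family, n_reps=None, variance_of_mean=True):
    """Model variance per group at the group mean from the final dispersion.

    ``mu_ik`` is (G, K); ``n_reps`` the per-group replicate counts, used
    when ``variance_of_mean`` to scale down to the variance of the mean.
    """
    mu_ik = np.asarray(mu_ik, dtype=float)
    d = np.asarray(disp_final, dtype=float)[:, None]
    if family == "nb":
        var = mu_ik + mu_ik**2 * d
    elif family == "dp":
        var = mu_ik / d
    else:
        raise ValueError(f"unknown family {family!r}")
    if variance_of_mean:
        if n_reps is None:
            raise ValueError("n_reps required when variance_of_mean=True")
        var = var / np.asarray(n_reps, dtype=float)[None, :]
    return var


def wald_statistic(mu_1, mu_2, sigma2_1, sigma2_2):
    """W = |mu1 - mu2| / sqrt(s1^2 + s2^2); inf when the denominator is
    zero but the means differ, 0 when both are degenerate and equal."""
    mu_1, mu_2, s1, s2 = np.broadcast_arrays(
        *[np.asarray(a, dtype=float) for a in (mu_1, mu_2, sigma2_1, sigma2_2)])
    if np.any(s1 < 0) or np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    denom = np.sqrt(s1 + s2)
    num = np.abs(mu_1 - mu_2)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = num / denom
    w = np.where(denom == 0.0, np.where(num == 0.0, 0.0, np.inf), w)
    return w if w.shape else float(w)


def wald_pvalue(w):
    """Two-sided p from the standard normal: p = 2 * (1 - Phi(W))."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("Wald statistic must be non-negative")
    p = 2.0 * norm.sf(w)
    p = np.minimum(p, 1.0)
    return p if p.shape else float(p)


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fold_change(norm_mean_1, norm_mean_2):
    """FC = mean2 / mean1 of normalized counts; 0/0 -> 1, x/0 -> inf."""
    m1, m2 = np.broadcast_arrays(*[np.asarray(a, dtype=float) for a in (norm_mean_1, norm_mean_2)])
    if np.any(m1 < 0) or np.any(m2 < 0):
        raise ValueError("means must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = m2 / m1
    fc = np.where(m1 == 0.0, np.where(m2 == 0.0, 1.0, np.inf), fc)
    return fc if fc.shape else float(fc)


def call_degs(padj, fc, alpha=0.05, fc_low=0.67, fc_high=1.5):
    """DEG rule: adjusted p < alpha AND (FC < fc_low OR FC > fc_high)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    padj = np.asarray(padj, dtype=float)
    fc = np.asarray(fc, dtype=float)
    return (padj < alpha) & ((fc < fc_low) | (fc > fc_high))
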