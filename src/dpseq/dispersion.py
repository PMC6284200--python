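"""Five-stage empirical-Bayes dispersion estimation.

With a handful of replicates per group, per-gene dispersion estimates are
far too noisy to test with directly.  The cascade stabilises them in five
stages, run separately for the NB family (dispersion ``phi``) and the DP
family (dispersion ``theta``):

1. **moments initialiser** — from the pooled per-gene mean and variance:
   ``phi_init = (sigma2 - mu) / mu^2`` (floored at 1e-8 when the gene is
   underdispersed, which the NB family cannot represent) and
   ``theta_init = mu / sigma2``.
2. **gene-wise MLE** — bounded 1-D maximum likelihood in log-dispersion,
   holding the fitted group means fixed.
3. **common trend** — a locally weighted (lowess) regression of
   log gene-wise dispersion on log mean, evaluated at every gene:
   genes of similar expression strength share a dispersion trend.
4. **log-normal shrinkage** — gene-wise dispersions are modelled as
   log-normal around the trend; the prior centre is the median of the
   log common dispersions and its width a MAD of the log residuals.
   Each gene's dispersion is re-estimated by MAP (likelihood plus
   log-prior), squeezing noisy estimates toward the prior.
5. **window scan** — genes are ranked by mean and walked in windows of
   one normalized count; within a window each gene is typed by whether
   its shrunk dispersion sits above (I) or below (II) the trend, and its
   final dispersion is the max (NB) or min (DP) of its own shrunk value
   and the median of its type.  The NB rule guards against variance
   underestimation, the DP rule against variance underestimation too
   (DP variance is mu/theta, so *smaller* theta means larger variance).

Dispersions are assumed shared between the two groups, so every stage
pools all ``n = K*J`` samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datasets import CountDataset
from .families import DP_THETA_MAX, DP_THETA_MIN, NB_PHI_MAX, NB_PHI_MIN
from .normalize import SizeFactors, normalize_counts

__all__ = [
    "LNPrior",
    "DispersionTable",
    "pooled_moments",
    "initial_dispersion",
    "group_means",
    "genewise_mle",
    "common_trend",
    "ln_prior",
    "shrink_dispersion",
    "window_scan_final",
    "estimate_dispersions",
]

logger = logging.getLogger(__name__)

TAU_FLOOR = 0.25
MAD_SCALE = 1.4826  # normal-consistency constant


def _bounds(family):
    if family == "nb":
        return NB_PHI_MIN, NB_PHI_MAX
    if family == "dp":
        return DP_THETA_MIN, DP_THETA_MAX
    raise ValueError(f"unknown family {family!r}; use 'nb' or 'dp'")


class LNPrior:
    """Log-normal shrinkage prior on the dispersion: log(disp) ~ N(m0, tau^2)."""

    def __init__(self, m0, tau):
        if tau < TAU_FLOOR:
            raise ValueError(f"tau below floor {TAU_FLOOR}")
        self.m0 = float(m0)
        self.tau = float(tau)

    def __repr__(self):
        return f"<LNPrior m0={self.m0:.4f} tau={self.tau:.4f}>"


class DispersionTable:
    """Per-gene record of all five dispersion stages for one family."""

    def __init__(self, frame: pd.DataFrame, family: str, prior: LNPrior):
        self.frame = frame
        self.family = family
        self.prior = prior

    @property
    def final(self):
        return self.frame["final"]

    def to_csv(self, path, sep="\t"):
        out = self.frame.copy()
        out.insert(0, "gene_id", out.index)
        out["family"] = self.family
        out.to_csv(path, sep=sep, index=False, float_format="%.6g")


# ----------------------------------------------------------------------
# stage 1: moments


def pooled_moments(dataset: CountDataset, size_factors: SizeFactors):
    """Per-gene pooled mean ``mu_i`` and variance ``sigma2_i``.

    The mean is the all-sample average of normalized counts scaled back
    by the average size factor; the variance is the df-weighted pooled
    *within-group* sample variance of normalized counts on the same
    scale, so a true group-mean difference does not inflate it.
    """
    dataset.require_replicates(2)
    x = normalize_counts(dataset, size_factors).to_numpy()
    s = size_factors.to_numpy()
    sbar = s.mean()
    mu = x.mean(axis=1) * sbar
    masks = dataset.group_masks()
    ss = np.zeros(x.shape[0])
    df = 0
    for mask in masks:
        xg = x[:, mask]
        ss += ((xg - xg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df += mask.sum() - 1
    sigma2 = sbar**2 * ss / df
    return mu, sigma2


def initial_dispersion(mu, sigma2, family):
    """Method-of-moments initialiser (stage 1 output)."""
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    lo, hi = _bounds(family)
    if family == "nb":
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = (sigma2 - mu) / mu**2
        return np.clip(np.where(np.isfinite(phi), phi, lo), lo, hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(sigma2 > 0, mu / sigma2, hi)
    return np.clip(theta, lo, hi)


# ----------------------------------------------------------------------
# fitted means


def group_means(dataset: CountDataset, size_factors: SizeFactors):
    """Group expectations ``mu_ik`` and per-sample fitted means ``mu_ijk``.

    ``mu_ik`` is the group average of normalized counts scaled by the
    group-average size factor; each sample's fitted mean re-applies its
    own size factor so observations keep their own depth.
    """
    x = normalize_counts(dataset, size_factors).to_numpy()
    s = size_factors.to_numpy()
    masks = dataset.group_masks()
    G, n = x.shape
    mu_ik = np.zeros((G, len(masks)))
    mu_ijk = np.zeros((G, n))
    for k, mask in enumerate(masks):
        xbar = x[:, mask].mean(axis=1)
        mu_ik[:, k] = xbar * s[mask].mean()
        mu_ijk[:, mask] = xbar[:, None] * s[None, mask]
    return mu_ik, mu_ijk


# ----------------------------------------------------------------------
# vectorised bounded maximisation in log-dispersion


def _golden_max(objective, a, b, n_iter=45):
    """Vectorised golden-section maximisation on per-gene brackets."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    for _ in range(n_iter):
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        left = objective(c) >= objective(d)
        a = np.where(left, a, c)
        b = np.where(left, d, b)
    return 0.5 * (a + b)


def _maximize_logdisp(objective, lo, hi, x_init, n_grid=41):
    """Coarse grid + golden refinement; never worse than the initialiser."""
    G = x_init.shape[0]
    xs = np.linspace(np.log(lo), np.log(hi), n_grid)
    vals = np.empty((n_grid, G))
    for i, x in enumerate(xs):
        vals[i] = objective(np.full(G, x))
    best = np.argmax(vals, axis=0)
    a = xs[np.maximum(best - 1, 0)]
    b = xs[np.minimum(best + 1, n_grid - 1)]
    x_hat = _golden_max(objective, a, b)
    x0 = np.clip(x_init, np.log(lo), np.log(hi))
    take_init = objective(x0) > objective(x_hat)
    if np.any(take_init):
        logger.debug("optimizer: initialiser retained for %d gene(s)", int(take_init.sum()))
    return np.where(take_init, x0, x_hat)


def _make_loglik(family, y, mu_s, group_masks=None):
    """Per-gene log-likelihood in x = log(dispersion); constants dropped.

    ``y`` and ``mu_s`` are (G, n); samples with a zero fitted mean are
    deterministic zeros and contribute nothing.

    When ``group_masks`` is given the Cox-Reid adjustment
    ``-0.5 * sum_k log(sum_j w_jk)`` (w the GLM working weight) is
    subtracted, compensating for the group means being estimated from
    the same counts; without it the dispersion-driven variance is
    underestimated by roughly n/(n-K).  Groups whose fitted mean is zero
    carry no estimated parameter and are skipped.
    """
    mask = mu_s > 0
    if group_masks is None:
        group_masks = []
    # number of groups with a positive fitted mean, per gene
    k_eff = np.zeros(y.shape[0])
    group_mu = []
    for gm in group_masks:
        pos = mask[:, gm].any(axis=1)
        k_eff += pos
        group_mu.append((gm, pos))

    if family == "dp":
        with np.errstate(divide="ignore", invalid="ignore"):
            ylogy = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0)), 0.0)
            term = -mu_s + np.where(y > 0, y * (1.0 + np.log(mu_s)) - ylogy, 0.0)
        A = np.where(mask, term, 0.0).sum(axis=1)  # <= 0 by concavity of y log(mu/y)
        n_eff = mask.sum(axis=1).astype(float)
        # DP working weight is mu*theta, so the CR term is (k_eff/2)*x + const
        half_n = 0.5 * (n_eff - k_eff)

        def obj(x):
            return half_n * x + np.exp(x) * A

        return obj

    logmu = np.where(mask, np.log(np.where(mask, mu_s, 1.0)), 0.0)

    def obj(x):
        phi = np.exp(x)[:, None]
        r = 1.0 / phi
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (
                gammaln(y + r)
                - gammaln(r)
                - r * np.log1p(mu_s * phi)
                + y * (logmu + x[:, None] - np.log1p(mu_s * phi))
            )
        out = np.where(mask, t, 0.0).sum(axis=1)
        # NB working weight mu/(1 + phi*mu)
        for gm, pos in group_mu:
            w = np.where(mask[:, gm], mu_s[:, gm] / (1.0 + mu_s[:, gm] * phi), 0.0)
            sw = w.sum(axis=1)
            out = out - np.where(pos, 0.5 * np.log(np.where(pos, sw, 1.0)), 0.0)
        return out

    return obj


def genewise_mle(counts, mu_ijk, disp_init, family, group_masks=None):
    """Stage 2: per-gene MLE of the dispersion at fixed group means.

    ``counts`` and ``mu_ijk`` are (G, n) arrays; returns a (G,) vector
    within the family bounds (boundary values allowed).  Passing the
    per-group sample masks enables the Cox-Reid adjustment for the
    fitted means (recommended; used by the pipeline).
    """
    lo, hi = _bounds(family)
    y = np.asarray(counts, dtype=float)
    obj = _make_loglik(family, y, np.asarray(mu_ijk, dtype=float), group_masks)
    x0 = np.log(np.clip(np.asarray(disp_init, dtype=float), lo, hi))
    return np.exp(_maximize_logdisp(obj, lo, hi, x0))


# ----------------------------------------------------------------------
# stage 3: mean-dispersion trend


def at_boundary(disp, family, rel=1e-3):
    """Genes whose dispersion sits at the optimisation bounds.

    Boundary values are numerical sentinels (e.g. the 1e-8 NB floor for
    underdispersed genes), not data; the trend and prior stages must not
    treat them as observed dispersions.
    """
    d = np.asarray(disp, dtype=float)
    lo, hi = _bounds(family)
    return (d <= lo * (1.0 + rel)) | (d >= hi * (1.0 - rel))


def common_trend(mu, disp_genewise, family, frac=0.3, keep=None):
    """Stage 3: lowess of log dispersion on log mean, at every gene.

    ``keep`` masks the genes the trend is fitted on (the pipeline
    excludes boundary estimates); the curve is still evaluated at every
    gene, constant beyond the fitted mean range.  Fewer than 50 usable
    genes: falls back to their median gene-wise dispersion.
    """
    mu = np.asarray(mu, dtype=float)
    d = np.asarray(disp_genewise, dtype=float)
    lo, hi = _bounds(family)
    if keep is None:
        keep = np.ones(mu.shape, dtype=bool)
    else:
        keep = np.asarray(keep, dtype=bool)
        if keep.sum() < 50:
            logger.warning(
                "common trend (%s): only %d interior genes; fitting on all genes",
                family, int(keep.sum()))
            keep = np.ones(mu.shape, dtype=bool)
    if mu.size < 50:
        logger.warning("common trend: only %d genes; using median gene-wise dispersion", mu.size)
        return np.full(mu.shape, np.clip(np.median(d[keep]), lo, hi))
    logmu = np.log(mu)
    logd = np.log(d)
    delta = 0.01 * (logmu.max() - logmu.min())
    curve = lowess(logd[keep], logmu[keep], frac=frac, it=3, delta=delta)
    fit = np.interp(logmu, curve[:, 0], curve[:, 1])
    # lowess can return NaN in degenerate cases
    if np.any(~np.isfinite(fit)):
        fit = np.where(np.isfinite(fit), fit, np.median(logd[keep]))
    return np.clip(np.exp(fit), lo, hi)


# ----------------------------------------------------------------------
# stage 4: shrinkage


def ln_prior(disp_genewise, disp_common, keep=None) -> LNPrior:
    """Hyperparameters of the log-normal prior.

    Centre: median of log common dispersions.  Width: normal-consistent
    MAD of the log-residuals (gene-wise minus common), floored at 0.25 so
    the prior never degenerates to a point mass.  ``keep`` restricts the
    estimation to interior (non-boundary) gene-wise estimates.
    """
    alpha = np.asarray(disp_genewise, dtype=float)
    beta = np.asarray(disp_common, dtype=float)
    if alpha.size == 0 or alpha.shape != beta.shape:
        raise ValueError("gene-wise and common dispersion vectors must be equal-length, non-empty")
    if np.any(alpha <= 0) or np.any(beta <= 0):
        raise ValueError("dispersions must be positive")
    if keep is not None:
        keep = np.asarray(keep, dtype=bool)
        if keep.any():
            alpha, beta = alpha[keep], beta[keep]
    m0 = float(np.median(np.log(beta)))
    r = np.log(alpha) - np.log(beta)
    tau = MAD_SCALE * float(np.median(np.abs(r - np.median(r))))
    return LNPrior(m0, max(tau, TAU_FLOOR))


def shrink_dispersion(counts, mu_ijk, disp_genewise, prior: LNPrior, family,
                      group_masks=None):
    """Stage 4: MAP estimate squeezing gene-wise dispersions to the prior.

    Maximises the (Cox-Reid adjusted, when ``group_masks`` is given)
    log-likelihood plus the log-prior of the log-dispersion (a
    Normal(m0, tau^2) on the log scale, i.e. the log-normal prior in its
    natural parameterisation) over the same bounds as stage 2.
    """
    lo, hi = _bounds(family)
    y = np.asarray(counts, dtype=float)
    ll = _make_loglik(family, y, np.asarray(mu_ijk, dtype=float), group_masks)
    inv2t2 = 1.0 / (2.0 * prior.tau**2)

    def obj(x):
        return ll(x) - (x - prior.m0) ** 2 * inv2t2

    x0 = np.log(np.clip(np.asarray(disp_genewise, dtype=float), lo, hi))
    return np.exp(_maximize_logdisp(obj, lo, hi, x0))


# ----------------------------------------------------------------------
# stage 5: window scan


def window_scan_final(mu, disp_shrinkage, disp_common, family,
                      window_width=1.0, min_genes=20, gene_ids=None):
    """Stage 5: windowed final dispersions.

    Genes are sorted by mean (ties broken by gene ID) and cut into
    consecutive windows of ``window_width`` normalized counts; windows
    holding fewer than ``min_genes`` genes are merged with the next one
    (trailing remainder merged backward).  Within each window, genes with
    shrunk dispersion at or above the trend are I-type, the rest II-type;
    each gene's final value is the max (NB) or min (DP) of its own shrunk
    dispersion and its type's median.

    Returns ``(final, window_id)`` in the input gene order.
    """
    mu = np.asarray(mu, dtype=float)
    shr = np.asarray(disp_shrinkage, dtype=float)
    com = np.asarray(disp_common, dtype=float)
    G = mu.size
    if gene_ids is None:
        gene_ids = np.arange(G)
    gene_ids = np.asarray(gene_ids)
    order = np.lexsort((gene_ids, mu))

    mu_s = mu[order]
    raw = np.floor((mu_s - mu_s[0]) / float(window_width)).astype(np.int64)
    # merge small windows forward, trailing remainder backward
    win = np.zeros(G, dtype=np.int64)
    wid = 0
    start = 0
    boundaries = np.flatnonzero(np.diff(raw)) + 1  # window starts (sorted order)
    edges = list(boundaries) + [G]
    for edge in edges:
        if edge - start >= min_genes:
            win[start:edge] = wid
            wid += 1
            start = edge
    if start < G:  # trailing remainder
        if wid == 0:
            win[start:G] = 0
            wid = 1
        else:
            win[start:G] = wid - 1

    pick = np.maximum if family == "nb" else np.minimum
    final_s = shr[order].copy()
    shr_s = shr[order]
    com_s = com[order]
    for w in range(wid):
        idx = np.flatnonzero(win == w)
        is_one = shr_s[idx] >= com_s[idx]
        for type_mask in (is_one, ~is_one):
            sub = idx[type_mask]
            if sub.size == 0:
                continue
            med = np.median(shr_s[sub])
            final_s[sub] = pick(shr_s[sub], med)

    final = np.empty(G)
    window_id = np.empty(G, dtype=np.int64)
    final[order] = final_s
    window_id[order] = win
    return final, window_id


# ----------------------------------------------------------------------
# orchestration


def estimate_dispersions(dataset: CountDataset, size_factors: SizeFactors,
                         family: str, window_width=1.0) -> DispersionTable:
    """Run the full five-stage cascade for one model family."""
    _bounds(family)
    mu, sigma2 = pooled_moments(dataset, size_factors)
    if np.any(mu <= 0):
        raise ValueError("genes with zero counts in all samples must be removed first")
    init = initial_dispersion(mu, sigma2, family)
    mu_ik, mu_ijk = group_means(dataset, size_factors)
    y = dataset.counts.to_numpy().astype(float)
    gmasks = dataset.group_masks()
    genewise = genewise_mle(y, mu_ijk, init, family, group_masks=gmasks)
    interior = ~at_boundary(genewise, family)
    common = common_trend(mu, genewise, family, keep=interior)
    prior = ln_prior(genewise, common, keep=interior)
    logger.info("%s prior: m0=%.4f tau=%.4f", family.upper(), prior.m0, prior.tau)
    shrink = shrink_dispersion(y, mu_ijk, genewise, prior, family, group_masks=gmasks)
    final, window_id = window_scan_final(
        mu, shrink, common, family, window_width=window_width,
        gene_ids=dataset.gene_ids.to_numpy())
    logger.info("%s window scan: %d windows over %d genes",
                family.upper(), int(window_id.max()) + 1, mu.size)
    frame = pd.DataFrame(
        {
            "mu": mu,
            "sigma2": sigma2,
            "init": init,
            "genewise": genewise,
            "common": common,
            "shrinkage": shrink,
            "final": final,
            "window_id": window_id,
        },
        index=dataset.gene_ids,
    )
    return DispersionTable(frame, family, prior)
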