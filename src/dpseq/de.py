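"""Two-group differential-expression model and its fitted results.

:class:`DEModel` is built from a :class:`~dpseq.datasets.CountDataset`
(or a DataFrame / file via the alternative constructors) and a mode:

``"dp"``
    double-Poisson family only — handles under-, equi- and
    overdispersed genes;
``"nb"``
    negative-binomial family only — the classical choice, conservative
    for underdispersed genes;
``"mix"``
    both families are fitted and each gene's p-value is the smaller of
    the two, taken *before* FDR adjustment.

``fit()`` runs: all-zero-gene filtering -> size factors -> the
five-stage dispersion cascade per family -> Wald test -> (mix: per-gene
min p) -> BH adjustment, and returns a :class:`DEResults` with the
per-gene table, dispersion tables, priors and a ``summary()``.
The analysis path contains no randomness.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import testing
from .datasets import CountDataset
from .dispersion import estimate_dispersions, pooled_moments
from .normalize import compute_size_factors, normalize_counts

__all__ = ["DEModel", "DEResults"]

logger = logging.getLogger(__name__)

MODES = ("dp", "nb", "mix")


class DEModel:
    """Differential-expression model for a two-group count dataset.

    Parameters
    ----------
    dataset : CountDataset
        Counts plus a two-level condition (first level = control).
    mode : {"dp", "nb", "mix"}
    normalization : str
        Size-factor method, default ``"tmm"``.
    variance_of_mean : bool
        Divide each group's model variance by its replicate number in
        the Wald denominator (default True); False uses the raw model
        variance at the group mean.
    window_width : float
        Width, in normalized counts, of the window-scan windows.
    """

    def __init__(self, dataset: CountDataset, mode="mix", normalization="tmm",
                 variance_of_mean=True, window_width=1.0):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if dataset.condition is None:
            raise ValueError("dataset needs a two-group condition factor")
        dataset.require_replicates(2)
        self.dataset = dataset
        self.mode = mode
        self.normalization = normalization
        self.variance_of_mean = variance_of_mean
        self.window_width = window_width

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, condition, **kwargs):
        return cls(CountDataset(counts, condition=condition), **kwargs)

    @classmethod
    def from_file(cls, path, condition, **kwargs):
        from .io import read_counts

        return cls(read_counts(path, condition=condition), **kwargs)

    # ------------------------------------------------------------------
    def fit(self) -> "DEResults":
        data, removed = self.dataset.drop_all_zero_genes()
        if len(removed):
            logger.info("filtered %d all-zero gene(s)", len(removed))
        if data.n_genes == 0:
            raise ValueError("no genes with nonzero counts")
        sf = compute_size_factors(data, self.normalization)
        x = normalize_counts(data, sf).to_numpy()
        masks = data.group_masks()
        n_reps = np.array([m.sum() for m in masks])
        xbar = np.column_stack([x[:, m].mean(axis=1) for m in masks])
        s = sf.to_numpy()
        mu_ik = np.column_stack(
            [xbar[:, k] * s[m].mean() for k, m in enumerate(masks)])

        families = {"dp": ["dp"], "nb": ["nb"], "mix": ["dp", "nb"]}[self.mode]
        disp_tables = {}
        pvals = {}
        stats = {}
        for fam in families:
            table = estimate_dispersions(data, sf, fam, window_width=self.window_width)
            var = testing.group_variances(
                mu_ik, table.final.to_numpy(), fam,
                n_reps=n_reps if self.variance_of_mean else None,
                variance_of_mean=self.variance_of_mean)
            w = testing.wald_statistic(mu_ik[:, 0], mu_ik[:, 1], var[:, 0], var[:, 1])
            pvals[fam] = testing.wald_pvalue(w)
            stats[fam] = w
            disp_tables[fam] = table

        if self.mode == "mix":
            p = np.minimum(pvals["dp"], pvals["nb"])
            w = np.where(pvals["dp"] <= pvals["nb"], stats["dp"], stats["nb"])
        else:
            p = pvals[families[0]]
            w = stats[families[0]]
        padj = testing.bh_adjust(p)
        fc = testing.fold_change(xbar[:, 0], xbar[:, 1])

        mu_i, sigma2_i = pooled_moments(data, sf)
        under = sigma2_i < mu_i

        frame = pd.DataFrame(index=data.gene_ids)
        frame["mu_1"] = mu_ik[:, 0]
        frame["mu_2"] = mu_ik[:, 1]
        frame["fc"] = fc
        with np.errstate(divide="ignore"):
            frame["log2fc"] = np.log2(fc)
        frame["W"] = w
        for fam in families:
            frame[f"pvalue_{fam}"] = pvals[fam]
        frame["pvalue"] = p
        frame["padj"] = padj
        frame["deg"] = testing.call_degs(padj, fc)
        frame["dispersion_class"] = np.where(under, "underdispersed", "non-underdispersed")

        return DEResults(self, frame, disp_tables, sf, removed, data)


class DEResults:
    """Fitted results: per-gene table, dispersions, size factors.

    Attributes
    ----------
    frame : DataFrame
        Per-gene results (group means, FC, W, p, padj, DEG flag,
        dispersion class, per-family p-values in mix mode).
    dispersions : dict of family -> DispersionTable
    size_factors : SizeFactors
    filtered_genes : Index of all-zero genes removed before analysis.
    """

    def __init__(self, model, frame, dispersions, size_factors, filtered_genes, data):
        self.model = model
        self.frame = frame
        self.dispersions = dispersions
        self.size_factors = size_factors
        self.filtered_genes = filtered_genes
        self._data = data

    # convenience accessors -------------------------------------------
    @property
    def pvalues(self):
        return self.frame["pvalue"]

    @property
    def padj(self):
        return self.frame["padj"]

    @property
    def deg(self):
        return self.frame["deg"]

    def call_degs(self, alpha=0.05, fc_low=0.67, fc_high=1.5):
        """Re-call DEGs at different thresholds without refitting."""
        return pd.Series(
            testing.call_degs(self.frame["padj"], self.frame["fc"], alpha, fc_low, fc_high),
            index=self.frame.index, name="deg")

    def summary(self) -> str:
        f = self.frame
        model = self.model
        lines = [
            "Two-group differential expression",
            "=" * 52,
            f"mode:                 {model.mode.upper()}",
            f"normalization:        {model.normalization}",
            f"samples:              {self._data.n_samples}"
            f" ({' vs '.join(map(str, self._data.levels))})",
            f"genes analyzed:       {len(f)}",
            f"genes filtered (0):   {len(self.filtered_genes)}",
            f"underdispersed:       {(f['dispersion_class'] == 'underdispersed').sum()}"
            f" ({100 * (f['dispersion_class'] == 'underdispersed').mean():.1f}%)",
        ]
        for fam, table in self.dispersions.items():
            lines.append(
                f"{fam.upper()} prior:             m0={table.prior.m0:.4f}, tau={table.prior.tau:.4f}")
        lines += [
            f"DEGs (padj<0.05, FC): {int(f['deg'].sum())}",
            f"min padj:             {f['padj'].min():.3g}",
            "=" * 52,
        ]
        return "\n".join(lines)

    def to_csv(self, path, sep="\t"):
        """Write the per-gene table; infinities rendered as 'Inf'."""
        out = self.frame.copy()
        out.insert(0, "gene_id", out.index)
        out["mode"] = self.model.mode
        out = out.replace([np.inf], "Inf")
        out.to_csv(path, sep=sep, index=False, float_format="%.6g", na_rep="NA")

    def __repr__(self):
        return (f"<DEResults mode={self.model.mode} genes={len(self.frame)} "
                f"degs={int(self.frame['deg'].sum())}>")
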