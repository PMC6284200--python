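"""Benchmark metrics over truth-labelled differential-expression results.

Given per-gene p-values and the simulator's ground truth, computes the
type-I error rate (FPR: fraction of truly non-DE genes with p below the
level), statistical power (TPR), ROC curve and AUC (rank-based, so ties
are handled as in the Mann-Whitney statistic), precision-recall curve,
and DEG counts.  Metrics can be stratified by the observed dispersion
class (underdispersed vs non-underdispersed), and external methods'
result tables — any delimited file with gene_id and pvalue columns —
can be scored side by side.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

__all__ = ["confusion_metrics", "roc_auc", "prc", "compare_methods", "read_result_table"]

logger = logging.getLogger(__name__)

STRATA = ("all", "underdispersed", "non-underdispersed")


def _aligned(p, truth_is_de):
    p = np.asarray(p, dtype=float)
    t = np.asarray(truth_is_de, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("p-values and truth labels are misaligned")
    return p, t


def confusion_metrics(p, truth_is_de, alpha=0.05):
    """FPR and TPR at level ``alpha``; NaN when a class is empty."""
    p, t = _aligned(p, truth_is_de)
    sig = p < alpha
    n_null = (~t).sum()
    n_de = t.sum()
    fpr = float((sig & ~t).sum() / n_null) if n_null else np.nan
    tpr = float((sig & t).sum() / n_de) if n_de else np.nan
    return {"fpr": fpr, "tpr": tpr}


def roc_auc(p, truth_is_de):
    """ROC curve (threshold sweep on p) and rank-based AUC.

    Scores are ``-p`` so smaller p ranks higher; ties contribute half,
    matching the Mann-Whitney formulation.  Raises on single-class truth.
    """
    p, t = _aligned(p, truth_is_de)
    if t.all() or not t.any():
        raise ValueError("ROC needs both DE and non-DE genes")
    fpr, tpr, _ = roc_curve(t, -p, drop_intermediate=False)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return curve, float(roc_auc_score(t, -p))


def prc(p, truth_is_de):
    """Precision-recall curve over the p-value sweep.

    Reports, for each achievable recall, the best precision any
    threshold attains at that recall (the efficient frontier of the
    sweep), so a perfect ranking shows precision 1 everywhere.  The
    recall-0 anchor carries the precision of the top-ranked tie group.
    """
    p, t = _aligned(p, truth_is_de)
    if not t.any():
        raise ValueError("PRC needs at least one DE gene")
    precision, recall, _ = precision_recall_curve(t, -p)
    # drop sklearn's (precision=1, recall=0) sentinel; order by recall
    precision, recall = precision[-2::-1], recall[-2::-1]
    top_precision = precision[0]  # highest threshold = top-ranked group
    frame = (pd.DataFrame({"recall": recall, "precision": precision})
             .groupby("recall", as_index=False)["precision"].max())
    if frame["recall"].iloc[0] > 0:
        frame = pd.concat(
            [pd.DataFrame({"recall": [0.0], "precision": [top_precision]}), frame],
            ignore_index=True)
    return frame


def read_result_table(path) -> pd.DataFrame:
    """Load an external method's table (gene_id + pvalue, padj optional)."""
    from .io import sniff_delimiter

    df = pd.read_csv(path, sep=sniff_delimiter(path))
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols or "pvalue" not in cols:
        raise ValueError(f"{path}: needs gene_id and pvalue columns")
    out = df.rename(columns={cols["gene_id"]: "gene_id", cols["pvalue"]: "pvalue"})
    return out.set_index("gene_id")


def compare_methods(result_tables, truth, strata_labels=None, alpha=0.05,
                    replicate=0, deg_caller=None) -> pd.DataFrame:
    """Score several methods' p-value tables against one truth table.

    Parameters
    ----------
    result_tables : mapping of method name -> DataFrame (indexed by gene
        with a ``pvalue`` column) or path to such a table.
    truth : SimTruth or DataFrame with an ``is_de`` column, gene index.
    strata_labels : Series of per-gene dispersion class, optional; adds
        stratified rows next to the "all" stratum.
    alpha : significance level for FPR/TPR.
    replicate : label echoed into the output rows.

    Genes missing from a method's table count as p = 1 (logged).

    Returns a tidy frame: method, stratum, replicate, metric, value.
    """
    truth_frame = truth.frame if hasattr(truth, "frame") else truth
    genes = truth_frame.index
    is_de = truth_frame["is_de"].to_numpy(dtype=bool)

    strata = {"all": np.ones(len(genes), dtype=bool)}
    if strata_labels is not None:
        lab = strata_labels.reindex(genes)
        strata["underdispersed"] = (lab == "underdispersed").to_numpy()
        strata["non-underdispersed"] = (lab == "non-underdispersed").to_numpy()

    rows = []
    for name, table in result_tables.items():
        if not isinstance(table, pd.DataFrame):
            table = read_result_table(table)
        pv = table["pvalue"].reindex(genes)
        n_missing = int(pv.isna().sum())
        if n_missing:
            logger.warning("%s: %d gene(s) missing from result table; treated as p=1",
                           name, n_missing)
            pv = pv.fillna(1.0)
        p = pv.to_numpy(dtype=float)
        for stratum, mask in strata.items():
            if not mask.any():
                continue
            cm = confusion_metrics(p[mask], is_de[mask], alpha=alpha)
            metrics = dict(cm)
            tm = is_de[mask]
            if tm.any() and not tm.all():
                _, metrics["auc"] = roc_auc(p[mask], tm)
            else:
                metrics["auc"] = np.nan
            if "padj" in table.columns:
                padj = table["padj"].reindex(genes).fillna(1.0).to_numpy(dtype=float)[mask]
                if "fc" in table.columns:
                    from .testing import call_degs

                    fc = table["fc"].reindex(genes).fillna(1.0).to_numpy(dtype=float)[mask]
                    metrics["n_deg"] = int(call_degs(padj, fc, alpha=alpha).sum())
                else:
                    metrics["n_deg"] = int((padj < alpha).sum())
            for metric, value in metrics.items():
                rows.append({"method": name, "stratum": stratum,
                             "replicate": replicate, "metric": metric, "value": value})
    return pd.DataFrame(rows)


def summarize_replicates(tidy: pd.DataFrame) -> pd.DataFrame:
    """Median of each metric across replicates (method x stratum x metric)."""
    return (tidy.groupby(["method", "stratum", "metric"])["value"]
            .median().rename("median").reset_index())
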