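"""Count-matrix container with a two-group design.

A :class:`CountDataset` holds a gene x sample matrix of non-negative
integer read counts together with an optional per-sample condition
factor.  Analyses require exactly two condition levels with at least two
replicates each; normalization-only workflows may omit the condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["CountDataset"]


class CountDataset:
    """Gene x sample integer count matrix plus a two-group condition.

    Parameters
    ----------
    counts : DataFrame or array_like
        Non-negative integers, genes as rows.  Arrays get default labels.
    condition : sequence of str, optional
        One label per sample with exactly two distinct levels.  The first
        level *in order of appearance* is treated as the control group;
        fold changes are reported as group2 / group1.
    """

    def __init__(self, counts, condition=None, gene_ids=None, sample_ids=None):
        if not isinstance(counts, pd.DataFrame):
            counts = np.asarray(counts)
            index = gene_ids if gene_ids is not None else [f"g{i+1}" for i in range(counts.shape[0])]
            cols = sample_ids if sample_ids is not None else [f"s{j+1}" for j in range(counts.shape[1])]
            counts = pd.DataFrame(counts, index=index, columns=cols)
        arr = counts.to_numpy()
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if np.any(arr != np.floor(arr)):
            raise ValueError("counts must be integers")
        if counts.index.duplicated().any():
            raise ValueError("duplicate gene IDs")
        if counts.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        self.counts = counts.astype(np.int64)

        if condition is not None:
            condition = list(condition)
            if len(condition) != counts.shape[1]:
                raise ValueError("condition length must match number of samples")
            levels = list(dict.fromkeys(condition))
            if len(levels) != 2:
                raise ValueError(f"exactly two condition levels required, got {levels}")
            self.condition = pd.Series(condition, index=counts.columns, name="condition")
            self.levels = levels
        else:
            self.condition = None
            self.levels = None

    # ------------------------------------------------------------------
    @property
    def gene_ids(self):
        return self.counts.index

    @property
    def sample_ids(self):
        return self.counts.columns

    @property
    def n_genes(self):
        return self.counts.shape[0]

    @property
    def n_samples(self):
        return self.counts.shape[1]

    def group_masks(self):
        """Boolean sample masks (control, treatment) in level order."""
        if self.condition is None:
            raise ValueError("dataset has no condition factor")
        cond = self.condition.to_numpy()
        return [cond == lev for lev in self.levels]

    def require_replicates(self, min_per_group=2):
        for lev, mask in zip(self.levels or [], self.group_masks() if self.condition is not None else []):
            if mask.sum() < min_per_group:
                raise ValueError(
                    f"group {lev!r} has {int(mask.sum())} replicate(s); "
                    f"at least {min_per_group} replicates per group are required"
                )
        if self.condition is None:
            raise ValueError("dataset has no condition factor")

    def drop_all_zero_genes(self):
        """Return (filtered dataset, index of removed genes)."""
        keep = self.counts.sum(axis=1) > 0
        removed = self.counts.index[~keep]
        sub = CountDataset(self.counts.loc[keep],
                           condition=None if self.condition is None else list(self.condition))
        return sub, removed

    def __repr__(self):
        cond = "no condition" if self.condition is None else f"levels={self.levels}"
        return f"<CountDataset {self.n_genes} genes x {self.n_samples} samples, {cond}>"
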