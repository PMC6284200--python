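"""Reading and writing delimited count matrices and result tables.

Count matrices are plain text: first column gene identifiers, header row
of sample identifiers, entries non-negative integers.  The delimiter is
auto-detected between tab and comma.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import CountDataset

__all__ = ["read_counts", "write_counts", "sniff_delimiter", "write_table"]


def sniff_delimiter(path) -> str:
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file")
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_counts(path, condition=None) -> CountDataset:
    """Read a delimited gene x sample count matrix into a CountDataset.

    Raises ValueError on duplicate gene IDs, non-integer or negative
    entries (naming the offending cell), or an empty file.
    """
    sep = sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows/columns")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene IDs {dups[:5]}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = np.argwhere(~np.vectorize(np.isreal)(arr))
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric entry at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    frac = arr - np.floor(arr)
    if np.any(frac != 0):
        r, c = np.argwhere(frac != 0)[0]
        raise ValueError(
            f"{path}: non-integer count {arr[r, c]} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    if np.any(arr < 0):
        r, c = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{path}: negative count {arr[r, c]} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    counts = pd.DataFrame(arr.astype(np.int64), index=df.index.astype(str), columns=df.columns.astype(str))
    return CountDataset(counts, condition=condition)


def write_counts(dataset: CountDataset, path, sep="\t"):
    df = dataset.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path, sep="\t"):
    """Write a results table: 6 significant digits, Inf/NA literal tokens."""
    df.to_csv(path, sep=sep, index=False, float_format="%.6g", na_rep="NA")
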