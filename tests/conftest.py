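import numpy as np
import pandas as pd
import pytest

from dpseq.datasets import CountDataset


@pytest.fixture
def small_dataset():
    """3 genes x 6 samples, two groups of three, hand-checkable."""
    counts = pd.DataFrame(
        {
            "c1": [8, 100, 0],
            "c2": [10, 110, 0],
            "c3": [12, 90, 0],
            "t1": [8, 300, 5],
            "t2": [10, 310, 6],
            "t3": [12, 290, 7],
        },
        index=["flat", "up", "onoff"],
    )
    return CountDataset(counts, condition=["ctl"] * 3 + ["trt"] * 3)


@pytest.fixture
def null_sim():
    """One seeded null DP dataset (no DE genes) at moderate size."""
    from dpseq.simulate import simulate_dataset, synth_params

    params = synth_params(800, seed=7)
    return simulate_dataset(params, n_de=0, seed=7)


def make_grid_params(mus, thetas, per_cell, prefix="g"):
    rows = [(m, t) for m in mus for t in thetas for _ in range(per_cell)]
    return pd.DataFrame(
        {"mu": [r[0] for r in rows], "theta": [r[1] for r in rows]},
        index=[f"{prefix}{i}" for i in range(len(rows))],
    )
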