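"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and the library
routines the package delegates to) so that agreement is evidence, not
tautology.
"""

import numpy as np


def bh_oracle(p):
    """Literal step-up Benjamini-Hochberg by double loop over sorted p."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj_sorted = np.empty(m)
    for k in range(m):  # position k (0-based) has rank k+1
        best = 1.0
        for j in range(k, m):
            best = min(best, min(1.0, m * sorted_p[j] / (j + 1)))
        adj_sorted[k] = best
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def mann_whitney_auc(p, is_de):
    """AUC as the pairwise probability that a DE gene outranks a non-DE
    gene when ranked by ascending p; ties count half."""
    p = np.asarray(p, dtype=float)
    is_de = np.asarray(is_de, dtype=bool)
    pos = p[is_de]
    neg = p[~is_de]
    wins = (pos[:, None] < neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)


def dp_pmf_by_summation(y, mu, theta, tail=1e-12):
    """Exact DP pmf at y via direct renormalised summation of the
    closed-form density, written independently of the package."""
    import math

    def log_f(k):
        out = 0.5 * math.log(theta) - theta * mu
        if k > 0:
            out += -k + k * math.log(k) - math.lgamma(k + 1)
            out += theta * k * (1.0 + math.log(mu) - math.log(k))
        return out

    ymax = int(max(50, mu + 20 * math.sqrt(mu / theta)))
    total = sum(math.exp(log_f(k)) for k in range(ymax + 1))
    while math.exp(log_f(ymax)) > tail * total:
        ymax *= 2
        total = sum(math.exp(log_f(k)) for k in range(ymax + 1))
    return math.exp(log_f(y)) / total
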