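"""Independent oracles for the exact Fisher test and BH adjustment.

Deliberately share no code with the implementations: probabilities come from
math.factorial and tables are enumerated cell-by-cell with a margin filter;
the BH oracle applies the step-up definition literally.
"""

import itertools
from math import factorial

import numpy as np


def fisher_oracle(table):
    """Brute-force exact Fisher p for an r x c count table."""
    t = np.asarray(table, dtype=int)
    rows, cols = t.shape
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    total = t.sum()

    def prob(cells):
        num = 1
        for r in row_sums:
            num *= factorial(r)
        for c in col_sums:
            num *= factorial(c)
        den = factorial(total)
        for x in cells:
            den *= factorial(x)
        return num / den

    ranges = [
        range(min(row_sums[i // cols], col_sums[i % cols]) + 1) for i in range(rows * cols)
    ]
    p_obs = prob(t.ravel())
    p = 0.0
    for cells in itertools.product(*ranges):
        m = np.array(cells).reshape(rows, cols)
        if (m.sum(axis=1) == row_sums).all() and (m.sum(axis=0) == col_sums).all():
            pm = prob(cells)
            if pm <= p_obs * (1 + 1e-7):
                p += pm
    return p


def bh_oracle(p):
    """Step-up false-discovery-rate definition applied literally."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for i_rank, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(i_rank, m)]
        out[idx] = min(1.0, min(candidates))
    return out
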