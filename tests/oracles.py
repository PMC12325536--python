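"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the logistic oracle is
a brute-force likelihood grid search, and the clumping oracle is a
set-based re-derivation working from a precomputed pandas correlation
matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def grid_logistic_mle(y, x, span: float = 8.0, grid: int = 41,
                      iterations: int = 10) -> tuple[float, float]:
    """Maximize the Bernoulli log-likelihood of ``logit p = b0 + b1 x``
    over a shrinking 2-D grid. Accurate to well below 1e-3 on tiny data."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    c0 = c1 = 0.0
    half0 = half1 = span
    for _ in range(iterations):
        b0s = np.linspace(c0 - half0, c0 + half0, grid)
        b1s = np.linspace(c1 - half1, c1 + half1, grid)
        eta = b0s[:, None, None] + b1s[None, :, None] * x[None, None, :]
        # stable log(1 + e^eta)
        ll = (y[None, None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        c0, c1 = b0s[i], b1s[j]
        half0 *= 3.0 / (grid - 1)
        half1 *= 3.0 / (grid - 1)
        half0 = max(half0, 1e-9)
        half1 = max(half1, 1e-9)
    return float(c0), float(c1)


def clump_oracle(stats, panel: pd.DataFrame, p_thresh: float,
                 r2_thresh: float, window_kb: float):
    """Set-based greedy clumping from a full pandas correlation matrix."""
    usable = [r for r in stats
              if r.p <= p_thresh and panel[r.snp_id].std(ddof=0) > 0]
    order = sorted(usable, key=lambda r: (r.p, str(r.chrom), r.pos, r.snp_id))
    r2 = panel.corr() ** 2
    index, removed, assigned = [], {}, set()
    for rec in order:
        if rec.snp_id in assigned:
            continue
        index.append(rec.snp_id)
        assigned.add(rec.snp_id)
        for other in order:
            if other.snp_id in assigned:
                continue
            if (str(other.chrom) == str(rec.chrom)
                    and abs(other.pos - rec.pos) <= window_kb * 1000.0
                    and r2.loc[rec.snp_id, other.snp_id] > r2_thresh):
                removed[other.snp_id] = rec.snp_id
                assigned.add(other.snp_id)
    return index, removed
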