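"""Exact dip statistic by linear programming — test-only oracle.

The dip of an empirical CDF is the smallest eps such that some unimodal
(convex-then-concave) CDF stays within an eps-tube around it.  For a mode at
sample point m this is a linear feasibility problem in the fitted CDF values
at the sample points; minimising eps per candidate mode and taking the best
mode gives the exact statistic.  O(n) LPs of size O(n) — fine for the small
samples used in tests, and entirely independent of the iterative
hull-narrowing algorithm in the package.
"""

import numpy as np
from scipy.optimize import linprog


def dip_lp(x) -> float:
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    best = np.inf
    for m in range(n):
        c = np.zeros(n + 1)
        c[-1] = 1.0
        A, b = [], []
        for i in range(n):
            # tube: (i+1)/n - eps <= g_i <= i/n + eps  (1-based CDF steps)
            row = np.zeros(n + 1)
            row[i], row[-1] = -1.0, -1.0
            A.append(row)
            b.append(-(i + 1) / n)
            row = np.zeros(n + 1)
            row[i], row[-1] = 1.0, -1.0
            A.append(row)
            b.append(i / n)
        for i in range(n - 1):  # monotone CDF
            row = np.zeros(n + 1)
            row[i], row[i + 1] = 1.0, -1.0
            A.append(row)
            b.append(0.0)
        for i in range(n - 2):  # slopes rise before the mode, fall after
            dx1, dx2 = x[i + 1] - x[i], x[i + 2] - x[i + 1]
            if dx1 == 0 or dx2 == 0:
                continue
            row = np.zeros(n + 1)
            row[i] = -1.0 / dx1
            row[i + 1] = 1.0 / dx1 + 1.0 / dx2
            row[i + 2] = -1.0 / dx2
            if i <= m - 2:
                A.append(row)
                b.append(0.0)
            if i >= m:
                A.append(-row)
                b.append(0.0)
        res = linprog(
            c,
            A_ub=np.array(A),
            b_ub=np.array(b),
            bounds=[(0.0, 1.0)] * n + [(0.0, None)],
            method="highs",
        )
        if res.success:
            best = min(best, res.fun)
    return float(best)
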