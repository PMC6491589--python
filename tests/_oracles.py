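"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its definition with plain
loops/sorts, sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def tmm_bruteforce(mat: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Doubly-trimmed precision-weighted mean of log-ratios, per column
    against the upper-quartile reference, rescaled to geometric mean 1."""
    mat = np.asarray(mat, float)
    n_prot, n_col = mat.shape
    lib = [sum(mat[:, k]) for k in range(n_col)]

    # reference: column whose 0.75 quantile of scaled intensities is closest
    # to the mean such quantile
    f75 = [np.quantile(mat[:, k], 0.75) / lib[k] for k in range(n_col)]
    ref = min(range(n_col), key=lambda k: abs(f75[k] - np.mean(f75)))

    factors = []
    for k in range(n_col):
        if k == ref:
            factors.append(1.0)
            continue
        m, a, w = [], [], []
        for g in range(n_prot):
            yk, yr = mat[g, k] / lib[k], mat[g, ref] / lib[ref]
            m.append(math.log2(yk / yr))
            a.append(0.5 * math.log2(yk * yr))
            var = (lib[k] - mat[g, k]) / (lib[k] * mat[g, k]) + (
                (lib[ref] - mat[g, ref]) / (lib[ref] * mat[g, ref])
            )
            w.append(1.0 / var)
        # rank-based double trim (1-based ranks, floor(n*trim)+1 .. n-floor(n*trim))
        rank_m = {i: r + 1 for r, i in enumerate(sorted(range(n_prot), key=lambda i: m[i]))}
        rank_a = {i: r + 1 for r, i in enumerate(sorted(range(n_prot), key=lambda i: a[i]))}
        lo_m = math.floor(n_prot * trim_m) + 1
        hi_m = n_prot + 1 - lo_m
        lo_a = math.floor(n_prot * trim_a) + 1
        hi_a = n_prot + 1 - lo_a
        num = den = 0.0
        for i in range(n_prot):
            if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a:
                num += w[i] * m[i]
                den += w[i]
        factors.append(2.0 ** (num / den))

    log_gm = sum(math.log(f) for f in factors) / n_col
    return np.array([f / math.exp(log_gm) for f in factors])


def bh_stepup_bruteforce(p) -> np.ndarray:
    """Literal Benjamini–Hochberg step-up: adjusted_(i) = min_{j>=i} m p_(j)/j,
    capped at 1, mapped back to input order."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = adj_sorted[rank]
    return np.array(out)


def ols_pinv_bruteforce(y: np.ndarray, x: np.ndarray):
    """OLS via the Moore–Penrose pseudo-inverse: coefficients, residual
    variance and the unscaled coefficient variances."""
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    df = x.shape[0] - np.linalg.matrix_rank(x)
    s2 = float(resid @ resid) / df if df > 0 else float("nan")
    v = np.diag(pinv @ pinv.T)
    return beta, s2, v


def matrix_rank_by_elimination(x: np.ndarray, tol: float = 1e-10) -> int:
    """Rank by Gaussian elimination with partial pivoting."""
    a = np.array(x, float)
    n_rows, n_cols = a.shape
    rank = 0
    row = 0
    for col in range(n_cols):
        piv = row + int(np.argmax(np.abs(a[row:, col]))) if row < n_rows else None
        if piv is None or abs(a[piv, col]) < tol:
            continue
        a[[row, piv]] = a[[piv, row]]
        a[row] = a[row] / a[row, col]
        for r in range(n_rows):
            if r != row:
                a[r] -= a[r, col] * a[row]
        rank += 1
        row += 1
        if row == n_rows:
            break
    return rank
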