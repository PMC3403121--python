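"""Independent reference computations used as test oracles.

Everything here is deliberately naive — closed forms, exhaustive loops,
direct sum-of-squares — and shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def anova_f_sum_of_squares(values: np.ndarray, member_idx: list[list[int]]) -> np.ndarray:
    """One-way ANOVA F per row from explicit between/within sums of squares."""
    F = np.empty(values.shape[0])
    k = len(member_idx)
    n = sum(len(m) for m in member_idx)
    for i, row in enumerate(values):
        grand = row[np.concatenate([np.array(m) for m in member_idx])].mean()
        ssb = sum(len(m) * (row[m].mean() - grand) ** 2 for m in member_idx)
        ssw = sum(((row[m] - row[m].mean()) ** 2).sum() for m in member_idx)
        F[i] = (ssb / (k - 1)) / (ssw / (n - k))
    return F


def affine_fit_max_residual(x: np.ndarray, r: np.ndarray) -> float:
    """Least-squares affine fit x ~ a*r + b via the 2x2 normal equations."""
    n = len(r)
    srr, sr, sx, srx = (r * r).sum(), r.sum(), x.sum(), (r * x).sum()
    det = n * srr - sr * sr
    a = (n * srx - sr * sx) / det
    b = (sx * srr - sr * srx) / det
    return float(np.max(np.abs(x - (a * r + b))))


def partial_corr_precision(x, y, z) -> float:
    """Partial correlation from the inverse of the 3x3 correlation matrix."""
    C = np.corrcoef(np.vstack([x, y, z]))
    P = np.linalg.inv(C)
    return float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))


def link_strength_triple_loop(g1, g2, values: np.ndarray, t0: int, t1: int) -> float:
    """Literal sum/max/min evaluation of the link-strength formula."""
    W = values[:, t0 : t1 + 1]

    def corr(a, b):
        return float(np.corrcoef(W[a], W[b])[0, 1])

    total = 0.0
    for X in sorted(g1):
        best = -np.inf
        for Y in sorted(g2):
            if X == Y:
                pair = 1.0
            else:
                vals = []
                for Z in sorted(g2):
                    if Z in (X, Y):
                        continue
                    cxy, cxz, cyz = corr(X, Y), corr(X, Z), corr(Y, Z)
                    if abs(cxz) >= 1 - 1e-12 or abs(cyz) >= 1 - 1e-12:
                        continue
                    vals.append(
                        (cxy - cxz * cyz) / math.sqrt((1 - cxz**2) * (1 - cyz**2))
                    )
                pair = min(vals) if vals else corr(X, Y)
            best = max(best, pair)
        total += best
    return total / len(g1)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(overlap >= k) by direct summation of the hypergeometric mass."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += (
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
        )
    return total


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, written out literally."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top  # 1-based rank of this p-value
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def member_certified(values, genes, start, end, epsilon, pattern_residual) -> bool:
    """Does some reference in `genes` certify all members over [start, end]?

    Uses the prefix-closed criterion (every prefix window within bound).
    """
    for r in genes:
        ok = True
        for g in genes:
            for t in range(start + 1, end + 1):
                if (
                    pattern_residual(
                        values[g, start : t + 1], values[r, start : t + 1], "shifting"
                    )
                    > epsilon
                ):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return True
    return False
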