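"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's computational paths: corrected LD
measures via explicit design-matrix regression and explicit matrix
inversion, Fisher p-values by exhaustive hypergeometric table enumeration,
and Hudson's Fst from pool allele counts.
"""

from __future__ import annotations

import math

import numpy as np


def brute_r2(xa, xb) -> float:
    c = np.corrcoef(np.asarray(xa, float), np.asarray(xb, float))[0, 1]
    return float(c * c)


def brute_r2_s(xa, xb, S) -> float:
    n = len(xa)
    X = np.column_stack([np.ones(n), np.asarray(S, float).reshape(n, -1)])
    beta_a, *_ = np.linalg.lstsq(X, np.asarray(xa, float), rcond=None)
    beta_b, *_ = np.linalg.lstsq(X, np.asarray(xb, float), rcond=None)
    ra = xa - X @ beta_a
    rb = xb - X @ beta_b
    return brute_r2(ra, rb)


def brute_r2_v(xa, xb, V) -> float:
    """Generalized correlation via explicit V^{-1} (intercept-only GLS)."""
    n = len(xa)
    Vinv = np.linalg.inv(np.asarray(V, float))
    one = np.ones(n)
    xa = np.asarray(xa, float)
    xb = np.asarray(xb, float)
    ga = (one @ Vinv @ xa) / (one @ Vinv @ one)
    gb = (one @ Vinv @ xb) / (one @ Vinv @ one)
    ra = xa - ga * one
    rb = xb - gb * one
    num = ra @ Vinv @ rb
    return float(num * num / ((ra @ Vinv @ ra) * (rb @ Vinv @ rb)))


def brute_r2_vs(xa, xb, S, V) -> float:
    """GLS residuals on [1, S] via the normal equations, then V-correlation."""
    n = len(xa)
    X = np.column_stack([np.ones(n), np.asarray(S, float).reshape(n, -1)])
    Vinv = np.linalg.inv(np.asarray(V, float))
    xa = np.asarray(xa, float)
    xb = np.asarray(xb, float)
    A = X.T @ Vinv @ X
    beta_a = np.linalg.solve(A, X.T @ Vinv @ xa)
    beta_b = np.linalg.solve(A, X.T @ Vinv @ xb)
    ra = xa - X @ beta_a
    rb = xb - X @ beta_b
    num = ra @ Vinv @ rb
    return float(num * num / ((ra @ Vinv @ ra) * (rb @ Vinv @ rb)))


def brute_fisher_two_sided(table) -> float:
    """Sum of hypergeometric probabilities of all tables with fixed margins
    that are no more probable than the observed one."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2_, c1 = a + b, c + d, a + c
    n = r1 + r2_

    def prob(k: int) -> float:
        return (
            math.comb(r1, k)
            * math.comb(r2_, c1 - k)
            / math.comb(n, c1)
        )

    lo = max(0, c1 - r2_)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


def hudson_fst(geno_pool1: np.ndarray, geno_pool2: np.ndarray) -> float:
    """Hudson's Fst (ratio of averages) from inbred dosage matrices.

    Each line counts as one haploid sequence; dosage 2 carries the
    alternate allele.
    """
    n1 = geno_pool1.shape[0]
    n2 = geno_pool2.shape[0]
    p1 = (geno_pool1 == 2).mean(axis=0)
    p2 = (geno_pool2 == 2).mean(axis=0)
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())
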