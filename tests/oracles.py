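"""Independent reference implementations used only as test oracles.

Everything here is written straight-line, without sharing code with the
package, so agreement between the two routes is meaningful evidence.
"""
from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# exact hypergeometric upper tail via integer arithmetic


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational arithmetic."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        if n - i > N - K:
            continue
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return float(acc)


# ---------------------------------------------------------------------------
# brute-force Pearson correlation


def pearson_matrix(X: np.ndarray) -> np.ndarray:
    """Gene x gene Pearson correlation computed from first principles."""
    n_genes, n_samples = X.shape
    C = np.zeros((n_genes, n_genes))
    for i in range(n_genes):
        for j in range(n_genes):
            xi = X[i] - X[i].mean()
            xj = X[j] - X[j].mean()
            denom = math.sqrt(float(xi @ xi) * float(xj @ xj))
            C[i, j] = float(xi @ xj) / denom if denom > 0 else 0.0
    return C


# ---------------------------------------------------------------------------
# straight-line re-implementation of the message-passing update equations


def _t(x, y):
    dot = sum(a * b for a, b in zip(x, y))
    den = sum(a * a for a in x) + sum(b * b for b in y) - abs(dot)
    return 0.0 if den <= 0 else dot / math.sqrt(den)


def _zscore(M):
    M = np.asarray(M, dtype=float)
    out = np.zeros_like(M)
    nr, nc = M.shape
    for i in range(nr):
        for j in range(nc):
            row = M[i, :]
            col = M[:, j]
            term = 0.0
            if row.std() > 0:
                term += (M[i, j] - row.mean()) / row.std()
            if col.std() > 0:
                term += (M[i, j] - col.mean()) / col.std()
            out[i, j] = term / math.sqrt(2.0)
    return out


def panda_reference(W0, P0, C0, alpha, tol, max_iter):
    """Naive loop-based message passing, mirroring the published update
    equations step by step.  Returns (W, iterations, final_hamming)."""
    W = _zscore(W0)
    P = _zscore(P0)
    C = _zscore(C0)
    nt, ng = W.shape
    hamming = float("inf")
    it = 0
    while it < max_iter:
        R = np.zeros((nt, ng))
        A = np.zeros((nt, ng))
        for i in range(nt):
            for j in range(ng):
                R[i, j] = _t(P[i, :], W[:, j])
                A[i, j] = _t(W[i, :], C[:, j])
        W_new = (1 - alpha) * W + alpha * (R + A) / 2.0

        coop = np.zeros((nt, nt))
        for i in range(nt):
            for j in range(nt):
                coop[i, j] = _t(W_new[i, :], W_new[j, :])
        coreg = np.zeros((ng, ng))
        for i in range(ng):
            for j in range(ng):
                coreg[i, j] = _t(W_new[:, i], W_new[:, j])
        for M, n in ((coop, nt), (coreg, ng)):
            if n > 1:
                for i in range(n):
                    off = [M[i, j] for j in range(n) if j != i]
                    mu = sum(off) / len(off)
                    sd = math.sqrt(sum((v - mu) ** 2 for v in off) / len(off))
                    M[i, i] = sd * n * math.exp(2.0 * alpha * it)
        P = (1 - alpha) * P + alpha * coop
        C = (1 - alpha) * C + alpha * coreg

        hamming = float(np.mean(np.abs(W_new - W)))
        W = W_new
        it += 1
        if hamming < tol:
            break
    return W, it, hamming


# ---------------------------------------------------------------------------
# brute-force TFCG extraction by subset enumeration (feasible for <= 12 TFs)


def tfcg_bruteforce(tf_ids, mutual_ok, threshold=None):
    """Greedy extraction over exhaustively enumerated valid subsets.

    ``mutual_ok(i, j)`` must say whether TFs i and j reciprocally share at
    least the threshold.  At each round, all subsets of the remaining TFs
    in which every pair is mutually ok and that are maximal within the
    remaining set are enumerated; the largest (lexicographically smallest
    member tuple on ties) is accepted and its TFs removed.
    """
    remaining = list(range(len(tf_ids)))
    groups = []
    while True:
        valid = []
        for r in range(2, len(remaining) + 1):
            for subset in combinations(remaining, r):
                if all(mutual_ok(a, b) for a, b in combinations(subset, 2)):
                    valid.append(set(subset))
        maximal = [
            s for s in valid
            if not any(s < t for t in valid)
        ]
        if not maximal:
            break
        best = min(
            maximal,
            key=lambda s: (-len(s), tuple(sorted(tf_ids[i] for i in s))),
        )
        groups.append({tf_ids[i] for i in best})
        remaining = [i for i in remaining if i not in best]
    return groups


# ---------------------------------------------------------------------------
# exact Mann-Whitney by enumeration of group assignments


def mann_whitney_enumeration(x, y):
    """Two-sided exact p by enumerating all C(nx+ny, nx) assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    combined = x + y
    nx = len(x)
    # midranks
    order = sorted(range(len(combined)), key=lambda i: combined[i])
    ranks = [0.0] * len(combined)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and combined[order[j]] == combined[order[i]]:
            j += 1
        avg = (i + j + 1) / 2.0
        for kk in range(i, j):
            ranks[order[kk]] = avg
        i = j
    const = nx * (nx + 1) / 2.0
    u_obs = sum(ranks[:nx]) - const
    us = []
    for idx in combinations(range(len(combined)), nx):
        us.append(sum(ranks[i] for i in idx) - const)
    eps = 1e-9
    le = sum(1 for u in us if u <= u_obs + eps)
    ge = sum(1 for u in us if u >= u_obs - eps)
    return u_obs, min(1.0, 2.0 * min(le, ge) / len(us))


# ---------------------------------------------------------------------------
# high-precision standard normal CDF via erf


def phi(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
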