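"""Independent reference implementations used only as test oracles.

Each deliberately takes a different computational route than the library:
recursive coancestry and Monte-Carlo gene dropping for the pedigree matrix
(vs the tabular method), dense GLS closed forms for BLUP (vs Henderson's
equations), a profiled likelihood grid for REML (vs EM/AI iteration), and
direct Monte Carlo of the father-sharing process (vs the genomic estimate).
"""
from __future__ import annotations

import math
from functools import lru_cache

import numpy as np


def recursive_kinship_A(parents: dict) -> tuple[list, np.ndarray]:
    """Numerator relationships by memoized coancestry recursion.

    ``parents`` maps id -> (dam, sire) with None for unknown. Returns ids in
    insertion order and A = 2 * kinship.
    """
    ids = list(parents)
    depth: dict = {}

    def get_depth(i):
        if i not in depth:
            d, s = parents[i]
            depth[i] = 1 + max(
                get_depth(d) if d is not None else -1,
                get_depth(s) if s is not None else -1,
            )
        return depth[i]

    @lru_cache(maxsize=None)
    def f(i, j):
        if i == j:
            d, s = parents[i]
            inner = f(*sorted((d, s))) if d is not None and s is not None else 0.0
            return 0.5 * (1.0 + inner)
        # recurse on the individual further from the founders
        if get_depth(i) < get_depth(j):
            i, j = j, i
        d, s = parents[i]
        out = 0.0
        if d is not None:
            out += 0.5 * f(*sorted((d, j)))
        if s is not None:
            out += 0.5 * f(*sorted((s, j)))
        return out

    n = len(ids)
    A = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            A[a, b] = A[b, a] = 2.0 * f(*sorted((ids[a], ids[b])))
    return ids, A


def gene_drop_A(parents: dict, n_reps: int, rng) -> tuple[list, np.ndarray]:
    """Monte-Carlo numerator relationships by dropping founder alleles."""
    ids = list(parents)
    order = []
    placed = set()
    pending = list(ids)
    while pending:  # simple repeated-pass topological sort
        rest = []
        for i in pending:
            d, s = parents[i]
            if (d is None or d in placed) and (s is None or s in placed):
                order.append(i)
                placed.add(i)
            else:
                rest.append(i)
        if len(rest) == len(pending):
            raise ValueError("cyclic pedigree")
        pending = rest

    alleles = {}
    label = iter(range(10**6))
    for i in order:
        d, s = parents[i]
        a = (
            np.full(n_reps, next(label))
            if d is None
            else np.where(rng.integers(0, 2, n_reps) == 0, *alleles[d])
        )
        b = (
            np.full(n_reps, next(label))
            if s is None
            else np.where(rng.integers(0, 2, n_reps) == 0, *alleles[s])
        )
        alleles[i] = (a, b)

    n = len(ids)
    A = np.zeros((n, n))
    for x in range(n):
        ax, bx = alleles[ids[x]]
        for y in range(x, n):
            ay, by = alleles[ids[y]]
            share = sum(
                np.mean(p == q) for p in (ax, bx) for q in (ay, by)
            ) / 4.0
            A[x, y] = A[y, x] = 2.0 * share
    return ids, A


def gls_blup(y, X, K_full, train_idx, s2a, s2e):
    """Closed-form GLS/BLUP: beta = (X'V^-1 X)^-1 X'V^-1 y and
    u = s2a * K Z' V^-1 (y - X beta), V = s2a Z K Z' + s2e I."""
    n = len(y)
    N = K_full.shape[0]
    Z = np.zeros((n, N))
    Z[np.arange(n), train_idx] = 1.0
    V = s2a * Z @ K_full @ Z.T + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = s2a * K_full @ Z.T @ Vi @ (y - X @ beta)
    return beta, u


def grid_reml_h2(y, K, step: float = 1e-3) -> float:
    """REML by brute-force profiled-likelihood grid over the heritability."""
    y = np.asarray(y, float)
    n = y.size
    X = np.ones((n, 1))
    p = 1
    best, best_h2 = -np.inf, np.nan
    for h2 in np.arange(step, 1.0, step):
        r = h2 / (1.0 - h2)
        V0 = r * K + np.eye(n)
        V0i = np.linalg.inv(V0)
        XtVX = X.T @ V0i @ X
        beta = np.linalg.solve(XtVX, X.T @ V0i @ y)
        resid = y - X @ beta
        q = float(resid @ V0i @ resid)
        s2e = q / (n - p)
        sign, ld0 = np.linalg.slogdet(V0)
        sign2, ldx = np.linalg.slogdet(XtVX)
        ll = -0.5 * ((n - p) * math.log(s2e) + ld0 + ldx + (n - p))
        if ll > best:
            best, best_h2 = ll, h2
    return best_h2


def father_share_probability(
    family_size: int, full_sib_fraction: float, n_reps: int, rng
) -> float:
    """Monte-Carlo probability that two random progeny of one dam share a
    father under the sequential copy-with-probability-f process."""
    share_sum = 0
    pair_count = 0
    n_pool = 10**9  # effectively collision-free pool of new fathers
    for _ in range(n_reps):
        fathers: list[int] = []
        for _k in range(family_size):
            if fathers and rng.random() < full_sib_fraction:
                fathers.append(fathers[rng.integers(len(fathers))])
            else:
                fathers.append(int(rng.integers(n_pool)))
        arr = np.array(fathers)
        same = (arr[:, None] == arr[None, :]).sum() - family_size
        share_sum += same / 2
        pair_count += family_size * (family_size - 1) / 2
    return share_sum / pair_count


def random_pedigree(rng, n: int) -> dict:
    """Random acyclic pedigree: each id is a founder or has parents among
    earlier ids (single known parents allowed)."""
    parents = {}
    ids = [f"p{k}" for k in range(n)]
    for k, i in enumerate(ids):
        if k < 2 or rng.random() < 0.3:
            parents[i] = (None, None)
        else:
            d = ids[rng.integers(k)]
            choice = rng.random()
            if choice < 0.25:
                parents[i] = (d, None)
            else:
                s = ids[rng.integers(k)]
                while s == d:
                    s = ids[rng.integers(k)]
                parents[i] = (d, s)
    return parents
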