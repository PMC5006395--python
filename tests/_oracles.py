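"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (double loops, O(n^3) agglomeration)
and shares no code with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def euclidean_double_loop(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = 0.0
            for v, w in zip(X[i], X[j]):
                s += (float(v) - float(w)) ** 2
            D[i, j] = s**0.5
    return D


def calinski_two_pass(X: np.ndarray, labels) -> float:
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    groups = sorted(set(labels.tolist()))
    k = len(groups)
    grand = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for g in groups:
        block = X[labels == g]
        cen = block.mean(axis=0)
        between += len(block) * float(((cen - grand) ** 2).sum())
        within += float(((block - cen) ** 2).sum())
    if within == 0:
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


def upgma_naive(D: np.ndarray) -> list[tuple[frozenset, float]]:
    """Exhaustive UPGMA: returns the merge sequence as (leaf set, height).

    At each step the pair of clusters with the smallest average inter-cluster
    distance is merged (ties: lexicographically smallest index pair, matching
    scipy's deterministic behaviour on the condensed ordering).
    """
    n = D.shape[0]
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    merges: list[tuple[frozenset, float]] = []
    active = dict(clusters)
    while len(active) > 1:
        best = None
        keys = sorted(active)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                vals = [D[x, y] for x in active[a] for y in active[b]]
                d = sum(vals) / len(vals)
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merged = active[a] | active[b]
        del active[a], active[b]
        active[len(clusters)] = merged
        clusters[len(clusters)] = merged
        merges.append((merged, d))
    return merges


def private_columns_scan(X: np.ndarray) -> list[int]:
    """Columns observed in exactly one row, by explicit scan."""
    out = []
    for j in range(X.shape[1]):
        carriers = [i for i in range(X.shape[0]) if X[i, j] == 1]
        if len(carriers) == 1:
            out.append(j)
    return out
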