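"""Independent brute-force oracles used by unit and acceptance tests.

Each function re-derives a statistic by direct enumeration or naive
recursion, deliberately sharing no code with the package implementation.
"""

from itertools import combinations

import numpy as np


def hypergeom_enrichment_p(N, K, n, k):
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) draws."""
    items = list(range(N))
    positives = set(range(K))
    total = hits = 0
    for draw in combinations(items, n):
        total += 1
        if len(positives.intersection(draw)) >= k:
            hits += 1
    return hits / total


def ward_linkage_heights(points):
    """Ward merge heights via the Lance-Williams recursion on distances."""
    points = [np.asarray(p, dtype=float) for p in points]
    n = len(points)
    dist = {}
    for i, j in combinations(range(n), 2):
        dist[(i, j)] = float(np.linalg.norm(points[i] - points[j]))
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    next_id = n
    heights = []

    def d(a, b):
        return dist[(min(a, b), max(a, b))]

    while len(active) > 1:
        (i, j) = min(combinations(sorted(active), 2), key=lambda ij: d(*ij))
        dij = d(i, j)
        heights.append(dij)
        ni, nj = sizes[i], sizes[j]
        for k in sorted(active - {i, j}):
            nk = sizes[k]
            dik, djk = d(i, k), d(j, k)
            new = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
            dist[(min(k, next_id), max(k, next_id))] = float(new)
        sizes[next_id] = ni + nj
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return heights


def gsea_running_sum_es(scores, member_flags, weight=1.0):
    """Enrichment score by an explicit element-by-element running sum."""
    N = len(scores)
    K = sum(member_flags)
    denom_hit = sum(abs(s) ** weight for s, m in zip(scores, member_flags) if m)
    running = 0.0
    best = 0.0
    for s, m in zip(scores, member_flags):
        if m:
            running += abs(s) ** weight / denom_hit
        else:
            running -= 1.0 / (N - K)
        if abs(running) > abs(best):
            best = running
    return best


def pc1_scores(matrix):
    """PC1 scores/loadings from an explicit eigendecomposition of the
    covariance matrix (column-centered input)."""
    X = np.asarray(matrix, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / len(X)
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, np.argmax(vals)]
    return Xc @ v, v


def pooled_t(x, y):
    """Classical two-sample pooled-variance t statistic, written out."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
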