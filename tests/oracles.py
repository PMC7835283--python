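"""Independent brute-force reference implementations used only by the tests.

These share no code with the package: bins, interpolation, linkage and the
step-up procedure are recomputed from their definitions with plain loops.
"""

import math
from itertools import product

import numpy as np


def h2_bruteforce(x, y, n_bins=10):
    """Direct-formula h²: explicit bin assignment, segment-by-segment
    piecewise-linear prediction, explained-variance ratio."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    lo, hi = min(x), max(x)
    edges = np.linspace(lo, hi, n_bins + 1)
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for xi, yi in zip(x, y):
        b = n_bins - 1
        for k in range(n_bins):
            if edges[k] <= xi < edges[k + 1]:
                b = k
                break
        sums[b] += yi
        counts[b] += 1
    pts = [(0.5 * (edges[k] + edges[k + 1]), sums[k] / counts[k])
           for k in range(n_bins) if counts[k] > 0]

    def predict(xi):
        if xi <= pts[0][0]:
            return pts[0][1]
        if xi >= pts[-1][0]:
            return pts[-1][1]
        for (m0, v0), (m1, v1) in zip(pts, pts[1:]):
            if m0 <= xi <= m1:
                return v0 + (v1 - v0) * (xi - m0) / (m1 - m0)
        raise AssertionError("unreachable")

    ybar = sum(y) / len(y)
    ss_res = sum((yi - predict(xi)) ** 2 for xi, yi in zip(x, y))
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def cosine_bruteforce(M):
    """Double-loop cosine similarity between matrix rows, zero rows -> 0."""
    n = len(M)
    S = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            dot = sum(M[i][k] * M[j][k] for k in range(len(M[i])))
            ni = math.sqrt(sum(v * v for v in M[i]))
            nj = math.sqrt(sum(v * v for v in M[j]))
            S[i][j] = dot / (ni * nj) if ni > 0 and nj > 0 else 0.0
    return np.array(S)


def average_linkage_bruteforce(labels, S):
    """Naive O(n^3) agglomeration: every step recomputes every cluster-pair
    average dissimilarity from the original matrix; ties resolved by the
    lexicographically smallest combined member tuple."""
    D = 1.0 - np.asarray(S, dtype=float)
    n = len(labels)
    clusters = {i: ([i], (labels[i],)) for i in range(n)}
    merges = []
    nid = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for p in range(len(ids)):
            for q in range(p + 1, len(ids)):
                a, b = ids[p], ids[q]
                ia, ib = clusters[a][0], clusters[b][0]
                d = sum(D[i][j] for i in ia for j in ib) / (len(ia) * len(ib))
                key = (d, tuple(sorted(clusters[a][1] + clusters[b][1])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _), a, b = best
        ca, cb = clusters.pop(a), clusters.pop(b)
        merges.append((a, b, d, len(ca[0]) + len(cb[0])))
        clusters[nid] = (ca[0] + cb[0], tuple(sorted(ca[1] + cb[1])))
        nid += 1
    return merges


def bh_stepup_bruteforce(pvalues, q):
    """Literal step-up: sort, find the largest i with p_(i) <= i q / m."""
    p = sorted(pvalues)
    m = len(p)
    cutoff = 0
    for i in range(1, m + 1):
        if p[i - 1] <= i * q / m:
            cutoff = i
    return cutoff


def signed_rank_exact_p(diffs):
    """Two-sided signed-rank p by exhaustive enumeration of all sign patterns
    (distinct nonzero |differences| assumed)."""
    d = [v for v in diffs if v != 0]
    n = len(d)
    order = sorted(range(n), key=lambda i: abs(d[i]))
    ranks = [0] * n
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    M = n * (n + 1) // 2
    dist = {}
    for signs in product([0, 1], repeat=n):
        w = sum(r * s for r, s in zip(range(1, n + 1), signs))
        dist[w] = dist.get(w, 0) + 1
    lo = sum(c for w, c in dist.items() if w <= min(w_obs, M - w_obs))
    hi = sum(c for w, c in dist.items() if w >= max(w_obs, M - w_obs))
    return min(1.0, (lo + hi) / 2 ** n)
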