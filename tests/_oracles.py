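"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately naive re-implementations (sum formulas, literal
definitions, O(n^3) agglomeration) kept free of the package's own code
paths.
"""

import itertools
import math

import numpy as np


def naive_pearson(x, y):
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def naive_median_of_ratios(matrix):
    rows = [r for r in matrix if all(v > 0 for v in r)]
    log_ref = [np.mean([np.log(v) for v in row]) for row in rows]
    sf = []
    for j in range(len(matrix[0])):
        ratios = [np.log(rows[i][j]) - log_ref[i] for i in range(len(rows))]
        sf.append(np.median(ratios))
    return np.exp(np.array(sf) - np.mean(sf))


def brute_force_bh(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adj[i] = min(running, 1.0)
    return adj


def naive_average_linkage_heights(points):
    clusters = [[i] for i in range(len(points))]
    dist = lambda a, b: math.dist(points[a], points[b])
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([dist(a, b) for a in clusters[i] for b in clusters[j]])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(heights)


def brute_force_changepoint(ratio, midpoints):
    """Literal scan over all one-changepoint step fits; midpoint interpolation."""
    ratio = np.asarray(ratio, dtype=float)
    m = ratio.size
    best, best_sse = None, np.inf
    for j in range(1, m):
        hi, lo = ratio[:j].mean(), ratio[j:].mean()
        sse = ((ratio[:j] - hi) ** 2).sum() + ((ratio[j:] - lo) ** 2).sum()
        if sse < best_sse:
            best, best_sse = j, sse
    return (midpoints[best - 1] + midpoints[best]) / 2.0
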