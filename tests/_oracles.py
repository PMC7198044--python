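"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (enumeration, O(n^2) pair counting,
textbook formulas) and shares no code with the package.
"""

from itertools import combinations
from math import erf, sqrt

import numpy as np


def point_in_polygon(px: float, py: float, vertices) -> bool:
    """Even-odd rule ray casting for a single point."""
    v = np.asarray(vertices, float)
    n = len(v)
    inside = False
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def rasterise_bruteforce(polygons, shape) -> np.ndarray:
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    for poly in polygons:
        for y in range(h):
            for x in range(w):
                if point_in_polygon(x + 0.5, y + 0.5, poly.vertices):
                    mask[y, x] = True
    return mask


def auc_bruteforce(pos, neg) -> float:
    wins = ties = 0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1
            elif x == y:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def youden_bruteforce(pos, neg):
    """Exhaustive J maximisation over midpoint thresholds plus +-inf;
    ties toward the lowest threshold."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    distinct = np.unique(np.concatenate([pos, neg]))
    thresholds = [-np.inf] + list((distinct[:-1] + distinct[1:]) / 2) + [np.inf]
    best = None
    for t in thresholds:
        sens = float((pos > t).mean())
        spec = float((neg <= t).mean())
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    return best  # (J, threshold, sens, spec)


def midranks(values) -> np.ndarray:
    v = np.asarray(values, float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size)
    i = 0
    sorted_v = v[order]
    while i < v.size:
        j = i
        while j < v.size and sorted_v[j] == sorted_v[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average of ranks i+1..j
        i = j
    return ranks


def kruskal_bruteforce(groups):
    """(H with tie correction, df) from first principles."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = pooled.size
    ranks = midranks(pooled)
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i : i + len(g)]
        h += r.sum() ** 2 / len(g)
        i += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    denom = 1.0 - float(np.sum(counts**3 - counts)) / (n**3 - n)
    if denom == 0:
        return 0.0, len(groups) - 1
    return h / denom, len(groups) - 1


def ranksum_W(x, y) -> float:
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = midranks(pooled)
    return float(min(ranks[: len(x)].sum(), ranks[len(x) :].sum()))


def ranksum_exact_p(x, y) -> float:
    """Exact two-sided p by enumerating every assignment of ranks to the
    first sample (valid with or without ties, via midranks)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = midranks(pooled)
    n1 = len(x)
    observed = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2.0
    dev = abs(observed - mean)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mean) >= dev - 1e-9:
            count += 1
    return count / total


def ranksum_normal_p(x, y) -> float:
    """Two-sided normal approximation with tie-corrected variance and
    continuity correction, from the textbook formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = midranks(pooled)
    w = ranks[:n1].sum()
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 1.0
    z = (abs(w - mean) - 0.5) / sqrt(var)
    return min(1.0, 2.0 * 0.5 * (1.0 - erf(max(z, 0.0) / sqrt(2.0))))


def bh_bruteforce(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up: p(i) * m / i with monotone enforcement."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * m / rank_from_top)
        adj[i] = prev
    return adj
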