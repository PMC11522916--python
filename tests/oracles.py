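"""Independent brute-force oracles used by unit and acceptance tests.

Everything here is deliberately slow and simple — plain Python loops and
exhaustive enumeration — so it shares no code path with the package
implementations it checks.
"""

import itertools
import math

import numpy as np


def hill_direct(p, q):
    p = [x for x in p if x > 0]
    if q == 1:
        return math.exp(-sum(x * math.log(x) for x in p))
    return sum(x**q for x in p) ** (1.0 / (1.0 - q))


def coverage_direct(counts):
    n = sum(counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    if f1 == 0:
        return 1.0
    if n == 1:
        return 0.0
    return 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2))


def expected_richness_enumeration(counts, m):
    """E[number of species in a size-m subsample], by full enumeration."""
    individuals = []
    for i, c in enumerate(counts):
        individuals.extend([i] * c)
    total = 0
    ndraws = 0
    for combo in itertools.combinations(range(len(individuals)), m):
        total += len({individuals[i] for i in combo})
        ndraws += 1
    return total / ndraws


def bray_curtis_direct(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def gower_direct(a, b, ranges):
    terms = [abs(x - y) / r for x, y, r in zip(a, b, ranges) if r > 0]
    return sum(terms) / len(terms)


def redundancy_5nn_direct(points, k=5):
    """Mean over points of the summed distances to the k nearest others."""
    pts = [list(map(float, p)) for p in points]
    sums = []
    for i, p in enumerate(pts):
        dists = sorted(
            math.dist(p, q) for j, q in enumerate(pts) if j != i
        )
        sums.append(sum(dists[:k]))
    return sum(sums) / len(sums)


def fdis_direct(points, weights):
    pts = np.asarray(points, float)
    w = np.asarray(weights, float)
    c = (w[:, None] * pts).sum(0) / w.sum()
    d = np.sqrt(((pts - c) ** 2).sum(1))
    return float((w * d).sum() / w.sum())


def pseudo_f_one_factor_direct(d, labels):
    """Classical PERMANOVA pseudo-F from group sums of squared distances."""
    d = np.asarray(d, float)
    n = d.shape[0]
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    groups = {}
    for i, g in enumerate(labels):
        groups.setdefault(g, []).append(i)
    ss_within = 0.0
    for idx in groups.values():
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    ss_among = ss_total - ss_within
    df1 = len(groups) - 1
    df2 = n - len(groups)
    return (ss_among / df1) / (ss_within / df2)


def lsd_letters_direct(means_desc, sig):
    """Maximal-interval letter display computed by exhaustive search."""
    k = len(means_desc)
    blocks = []
    for i in range(k):
        for j in range(i, k):
            idx = list(range(i, j + 1))
            if any(sig[a][b] for a in idx for b in idx if a != b):
                continue
            blocks.append((i, j))
    maximal = [
        (a, b)
        for a, b in blocks
        if not any((c <= a and b <= d) and (c, d) != (a, b) for c, d in blocks)
    ]
    maximal.sort()
    letters = ["" for _ in range(k)]
    for li, (a, b) in enumerate(maximal):
        for g in range(a, b + 1):
            letters[g] += "abcdefghijklmnopqrstuvwxyz"[li]
    return letters
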