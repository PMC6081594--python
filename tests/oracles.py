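"""Independent reference implementations used only by tests.

These deliberately avoid the library code paths they check: a full
dynamic-programming matrix for edit distance, and a direct
Lance–Williams recursion on squared distances for Ward.D2.
"""
from __future__ import annotations

import itertools

import numpy as np


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook full-matrix edit distance."""
    m, n = len(a), len(b)
    d = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        d[i][0] = i
    for j in range(n + 1):
        d[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1,
                          d[i - 1][j - 1] + cost)
    return d[m][n]


def ward_d2_merges(x: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Agglomerative Ward.D2 by direct Lance–Williams recursion.

    Operates on squared Euclidean distances; merge heights are reported
    on the (unsquared) distance scale. Returns (members_a, members_b,
    height) per merge, with members as frozensets of row indices.
    """
    n = len(x)
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    size = {i: 1 for i in range(n)}
    d2 = {}
    for i, j in itertools.combinations(range(n), 2):
        d2[(i, j)] = float(np.sum((x[i] - x[j]) ** 2))

    def get(i, j):
        return d2[(i, j) if i < j else (j, i)]

    merges = []
    next_id = n
    while len(clusters) > 1:
        (i, j) = min(((i, j) for i, j in itertools.combinations(
            sorted(clusters), 2)), key=lambda ij: get(*ij))
        h2 = get(i, j)
        merges.append((clusters[i], clusters[j], float(np.sqrt(h2))))
        new = next_id
        next_id += 1
        ni, nj = size[i], size[j]
        for k in sorted(clusters):
            if k in (i, j):
                continue
            nk = size[k]
            val = ((ni + nk) * get(i, k) + (nj + nk) * get(j, k)
                   - nk * h2) / (ni + nj + nk)
            d2[(min(k, new), max(k, new))] = val
        clusters[new] = clusters[i] | clusters[j]
        size[new] = ni + nj
        del clusters[i], clusters[j]
    return merges


def random_dna(rng, length: int, gc: float = 0.37) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
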