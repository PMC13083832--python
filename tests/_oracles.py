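"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, direct
formula evaluation — and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_segregating(calls: np.ndarray) -> tuple[int, int]:
    """(S, n_multiallelic) by per-site set cardinality of non-missing alleles."""
    S = multi = 0
    for site in calls:
        alleles = {int(a) for pair in site for a in pair if a >= 0}
        if len(alleles) >= 2:
            S += 1
        if len(alleles) >= 3:
            multi += 1
    return S, multi


def brute_pi_total(calls: np.ndarray) -> float:
    """Sum over sites of the mean pairwise categorical difference, enumerating
    every chromosome pair with per-site non-missing denominators."""
    total = 0.0
    for site in calls:
        chroms = [int(a) for pair in site for a in pair if a >= 0]
        pairs = list(itertools.combinations(chroms, 2))
        if pairs:
            total += sum(a != b for a, b in pairs) / len(pairs)
    return total


def harmonic(k: int) -> float:
    return sum(1.0 / i for i in range(1, k + 1))


def tajima_d_direct(m: int, S: int, pi_total: float) -> float:
    """Tajima (1989) D straight from the published constants."""
    a1 = harmonic(m - 1)
    a2 = sum(1.0 / i**2 for i in range(1, m))
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m * m + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi_total - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def brute_average_linkage(dist: np.ndarray) -> list[float]:
    """Merge heights of exhaustive average-linkage agglomeration on a
    condensed-to-square distance matrix. Returns sorted merge heights."""
    n = dist.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        heights.append(float(d))
        next_id += 1
    return sorted(heights)


def brute_mst_weight(vectors: list[tuple[int, ...]]) -> int:
    """Minimum spanning tree weight under Hamming distance by exhaustive
    enumeration of all spanning trees (edge subsets of size n-1)."""
    n = len(vectors)
    if n <= 1:
        return 0
    edges = [
        (i, j, sum(x != y for x, y in zip(vectors[i], vectors[j])))
        for i, j in itertools.combinations(range(n), 2)
    ]
    best = None
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for u, v, _ in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[rv] = ru
        if ok:
            w = sum(e[2] for e in subset)
            if best is None or w < best:
                best = w
    return best


def grid_loglik_pab(counts: np.ndarray, n_grid: int = 2001):
    """Grid search of the two-locus likelihood over p_AB (marginals fixed).

    Returns (best_pab, best_loglik) — the independent check that EM found the
    global maximum."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    lo, hi = max(0.0, pA + pB - 1.0), min(pA, pB)
    best = (None, -math.inf)
    for pab_ in np.linspace(lo, hi, n_grid):
        pAB, pAb, paB, pab = pab_, pA - pab_, pB - pab_, 1 - pA - pB + pab_
        probs = {
            (2, 2): pAB**2, (2, 1): 2 * pAB * pAb, (2, 0): pAb**2,
            (1, 2): 2 * pAB * paB, (1, 1): 2 * pAB * pab + 2 * pAb * paB,
            (1, 0): 2 * pAb * pab, (0, 2): paB**2, (0, 1): 2 * paB * pab,
            (0, 0): pab**2,
        }
        ll = 0.0
        for key, p in probs.items():
            c = counts[key]
            if c:
                if p <= 0:
                    ll = -math.inf
                    break
                ll += c * math.log(p)
        if ll > best[1]:
            best = (pab_, ll)
    return best
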