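"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the Ward oracle
recomputes every candidate merge height from scratch from the original
distance matrix via the centroid identity (never the Lance-Williams
recurrence), and the auROC oracle enumerates all (positive, negative) pairs.
"""

from __future__ import annotations

import numpy as np


def ward_linkage_from_scratch(S: np.ndarray, A: list[int], B: list[int]) -> float:
    """Ward merge cost of clusters A, B from the original (transformed)
    distance matrix S, via the centroid decomposition:

    ||c_A - c_B||^2 = mean cross term - within-A term - within-B term,
    height^2 = 2 |A||B|/(|A|+|B|) * ||c_A - c_B||^2.
    """
    a, b = len(A), len(B)
    cross = sum(S[i, j] for i in A for j in B) / (a * b)
    within_a = sum(S[i, j] for i in A for j in A) / (2 * a * a)
    within_b = sum(S[i, j] for i in B for j in B) / (2 * b * b)
    return 2.0 * (a * b / (a + b)) * (cross - within_a - within_b)


def ward_agglomerate_oracle(D: np.ndarray, variant: str = "ward.D2") -> np.ndarray:
    """O(n^4) agglomeration: at every step recompute all pairwise cluster
    linkages from scratch, merge the minimum (ties: smallest id pair).

    Returns an (n-1, 4) merge table in the same convention as the package:
    leaves 0..n-1, step-t cluster id n+t, columns (left, right, height, size).
    """
    n = D.shape[0]
    S = D.astype(float) ** 2 if variant == "ward.D2" else D.astype(float)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if j <= i:
                    continue
                h2 = ward_linkage_from_scratch(S, clusters[i], clusters[j])
                if (best is None or h2 < best[0]
                        or (h2 == best[0] and (i, j) < (best[1], best[2]))):
                    best = (h2, i, j)
        h2, i, j = best
        height = np.sqrt(h2) if variant == "ward.D2" else h2
        new = n + step
        merges[step] = (i, j, height, len(clusters[i]) + len(clusters[j]))
        clusters[new] = clusters.pop(i) + clusters.pop(j)
    return merges


def auroc_pairwise_oracle(scores, labels) -> float:
    """Mean over all (positive, negative) pairs of win + half-tie."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_euclidean_distance_matrix(rng: np.random.Generator, n: int,
                                     dim: int = 3) -> np.ndarray:
    """Random symmetric distance matrix from points in R^dim (so that Ward
    merge costs are guaranteed non-negative at every step)."""
    X = rng.normal(size=(n, dim))
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))
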