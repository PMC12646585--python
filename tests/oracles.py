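"""Independent brute-force reference computations used by the tests.

These deliberately avoid the code paths of the package: binomial-tail
bisection instead of beta quantiles, naive agglomerative clustering instead
of scipy's linkage, covariance eigendecomposition instead of SVD.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom


def binomial_ci_bisection(x: int, n: int, level: float = 0.95, tol: float = 1e-12):
    """Exact binomial CI by direct inversion of the binomial tails."""
    alpha = 1.0 - level

    def _solve(f, lo, hi):
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid):
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return 0.5 * (lo + hi)

    if x == 0:
        lower = 0.0
    else:
        # Largest p with P(X >= x | p) <= alpha/2.
        lower = _solve(lambda p: binom.sf(x - 1, n, p) <= alpha / 2.0, 0.0, 1.0)
    if x == n:
        upper = 1.0
    else:
        # Smallest p with P(X <= x | p) <= alpha/2 -> invert the complement.
        upper = 1.0 - _solve(
            lambda q: binom.cdf(x, n, 1.0 - q) <= alpha / 2.0, 0.0, 1.0
        )
    return lower, upper


def naive_average_linkage(points: np.ndarray):
    """Brute-force agglomerative clustering with average linkage and
    euclidean distance.  Returns the merge history as a list of
    (frozenset_a, frozenset_b, distance)."""
    clusters = [frozenset([i]) for i in range(len(points))]

    def dist(a: frozenset, b: frozenset) -> float:
        return float(
            np.mean(
                [np.linalg.norm(points[i] - points[j]) for i in a for j in b]
            )
        )

    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if best is None or d < best[2]:
                    best = (i, j, d)
        i, j, d = best
        merged = clusters[i] | clusters[j]
        merges.append((clusters[i], clusters[j], d))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def naive_two_cut(points: np.ndarray) -> list[frozenset]:
    """The two-cluster partition implied by the brute-force dendrogram."""
    merges = naive_average_linkage(points)
    a, b, _ = merges[-1]
    return [a, b]


def pca_scores_eigh(X: np.ndarray) -> np.ndarray:
    """Principal-component scores via eigendecomposition of the covariance
    matrix (columns ordered by decreasing eigenvalue)."""
    centered = X - X.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return centered @ v[:, order]


def class_centroids(X: np.ndarray, y: np.ndarray) -> dict:
    """Per-class feature means, the long way."""
    out = {}
    for cls in sorted(set(y)):
        rows = [X[i] for i in range(len(y)) if y[i] == cls]
        out[cls] = np.array([sum(col) / len(rows) for col in zip(*rows)])
    return out
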