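"""Independent brute-force oracles used to validate the implementations.

These deliberately share no code with the package: the Ward oracle
recomputes the within-cluster sum-of-squares increase for every cluster
pair at every step, and the rank-sum oracle enumerates all arrangements of
the pooled sample.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def sse(points: np.ndarray) -> float:
    centroid = points.mean(axis=0)
    return float(((points - centroid) ** 2).sum())


def ward_brute_force(X: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Full Ward agglomeration by exhaustive dSSE recomputation.

    Returns the merge sequence as (members_a, members_b, delta_sse).
    """
    clusters: dict[int, frozenset] = {i: frozenset([i]) for i in range(len(X))}
    merges = []
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            members = clusters[a] | clusters[b]
            delta = (
                sse(X[sorted(members)])
                - sse(X[sorted(clusters[a])])
                - sse(X[sorted(clusters[b])])
            )
            if best is None or delta < best[0]:
                best = (delta, a, b)
        delta, a, b = best
        merges.append((clusters[a], clusters[b], delta))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges


def mwu_exact_p(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided") -> float:
    """Exact Mann-Whitney p-value by enumerating all pooled arrangements.

    U is counted for x (pairs with x > y); inputs must be tie-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == n + m, "oracle requires tie-free data"
    u_obs = sum(xi > yj for xi in x for yj in y)

    order = np.argsort(pooled)
    u_values = []
    for x_positions in combinations(range(n + m), n):
        x_set = set(x_positions)
        # ranks of x among pooled, counting how many y lie below each x
        u = 0
        n_y_below = 0
        for pos in range(n + m):
            if pos in x_set:
                u += n_y_below
            else:
                n_y_below += 1
        u_values.append(u)
    u_values = np.array(u_values)
    total = len(u_values)
    p_leq = (u_values <= u_obs).sum() / total
    p_geq = (u_values >= u_obs).sum() / total
    if alternative == "less":
        return p_leq
    if alternative == "greater":
        return p_geq
    return min(1.0, 2.0 * min(p_leq, p_geq))
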