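"""Independent brute-force agglomerative clustering oracle for tests.

O(n^3) greedy agglomeration from first principles: at every step the
pair of active clusters at minimal linkage distance merges (ties broken
by the lowest-index pair), with inter-cluster distance recomputed
directly from all leaf pairs.  Deliberately naive and separate from the
implementation under test.
"""

from __future__ import annotations

import numpy as np


def brute_force_merges(
    X: np.ndarray, method: str = "complete"
) -> list[tuple[frozenset[int], float]]:
    """Return the merge sequence as (leaf set of new cluster, height)."""
    n = len(X)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = sorted(clusters)
    next_id = n
    merges: list[tuple[frozenset[int], float]] = []

    def dist(a: int, b: int) -> float:
        ds = [
            float(np.linalg.norm(X[i] - X[j]))
            for i in clusters[a]
            for j in clusters[b]
        ]
        if method == "complete":
            return max(ds)
        if method == "single":
            return min(ds)
        if method == "average":
            return sum(ds) / len(ds)
        raise ValueError(method)

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                d = dist(a, b)
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        active = sorted(set(active) - {a, b} | {next_id})
        merges.append((frozenset(clusters[next_id]), d))
        next_id += 1
    return merges


def scipy_merges(Z: np.ndarray, n: int) -> list[tuple[frozenset[int], float]]:
    """Convert a linkage matrix into the same (leaf set, height) encoding."""
    leaves: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_idx, (a, b, d, _) in enumerate(Z):
        merged = leaves[int(a)] | leaves[int(b)]
        leaves[n + row_idx] = merged
        merges.append((merged, float(d)))
    return merges
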