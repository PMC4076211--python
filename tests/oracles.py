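"""Independent brute-force reference implementations used as test oracles.

Deliberately written in plain Python loops, with no shared code paths
with the package, so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math


def fnn_fraction_oracle(
    x,
    m: int,
    tau: int = 1,
    r_tol: float = 10.0,
    a_tol: float = 2.0,
    norm: str = "euclidean",
    duplicate_rtol: float = 1e-10,
) -> float:
    """All-pairs false-nearest-neighbour fraction.

    Mirrors the documented contract: candidates are the points that
    extend to dimension m+1, self-matches and near-duplicate states
    (distance <= duplicate_rtol * sigma) are excluded, ties break toward
    the smallest index, and a neighbour is false under the distance-ratio
    OR the attractor-size criterion.
    """
    x = [float(v) for v in x]
    n = len(x)
    n_test = n - m * tau
    if n_test < 2:
        raise ValueError("series too short")
    mean = sum(x) / n
    sigma = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    if sigma == 0.0:
        raise ValueError("constant series")

    def point(i: int) -> list[float]:
        return [x[i + j * tau] for j in range(m)]

    def dist(p: list[float], q: list[float]) -> float:
        if norm == "euclidean":
            return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
        return max(abs(a - b) for a, b in zip(p, q))

    n_false = 0
    n_testable = 0
    for i in range(n_test):
        best_j, best_d = None, math.inf
        for j in range(n_test):
            if j == i:
                continue
            d = dist(point(i), point(j))
            if d <= duplicate_rtol * sigma:
                continue
            if d < best_d:  # strict: ties keep the smallest index
                best_d, best_j = d, j
        if best_j is None:
            continue
        n_testable += 1
        extra = abs(x[i + m * tau] - x[best_j + m * tau])
        if norm == "euclidean":
            d_m1 = math.sqrt(best_d**2 + extra**2)
        else:
            d_m1 = max(best_d, extra)
        if extra / best_d > r_tol or d_m1 / sigma > a_tol:
            n_false += 1
    if n_testable == 0:
        raise ValueError("no testable points")
    return n_false / n_testable


def transitivity_oracle(adjacency) -> float:
    """Global transitivity by direct enumeration of ordered triples."""
    n = len(adjacency)
    closed = 0
    paths = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if i == k:
                    continue
                if adjacency[i][j] and adjacency[j][k]:
                    paths += 1
                    if adjacency[k][i]:
                        closed += 1
    if paths == 0:
        raise ValueError("no length-2 paths")
    return closed / paths


def ranksum_exact_oracle(values_a, values_b) -> float:
    """Two-sided rank-sum p-value by exhaustive permutation of group
    assignments, midranks for ties."""
    pooled = [float(v) for v in values_a] + [float(v) for v in values_b]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    n_a = len(values_a)
    observed = sum(ranks[:n_a])
    mean_w = sum(ranks) * n_a / len(pooled)
    obs_dev = abs(observed - mean_w)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        w = sum(ranks[i] for i in combo)
        if abs(w - mean_w) >= obs_dev - 1e-9:
            count += 1
        total += 1
    return count / total


def tile_oracle(free_intervals, w: int, step: int) -> list[tuple[int, int]]:
    """Windows of length w inside each free interval: stride ``step`` from
    the left edge plus the flush-right window."""
    out = []
    for start, end in free_intervals:
        if end - start < w:
            continue
        s = start
        starts = []
        while s <= end - w:
            starts.append(s)
            s += step
        if starts[-1] != end - w:
            starts.append(end - w)
        out.extend((s, s + w) for s in starts)
    return out
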