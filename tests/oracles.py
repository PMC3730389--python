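"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by the most literal method available
(path enumeration, matrix powering, exhaustive loops) without touching the
implementation under test.
"""

from __future__ import annotations

import numpy as np


def all_shortest_paths_betweenness(edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw and normalized betweenness by exhaustive simple-path enumeration.

    For every unordered pair (s, t), enumerates all simple paths by DFS,
    keeps the shortest ones, and credits each interior node with its fraction
    of those geodesics.  Exponential; only for tiny graphs.
    """
    n = edges.shape[0]
    raw = np.zeros(n)
    adj = [np.flatnonzero(edges[v]).tolist() for v in range(n)]

    def simple_paths(s: int, t: int) -> list[list[int]]:
        out: list[list[int]] = []
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                out.append(path)
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return out

    for s in range(n):
        for t in range(s + 1, n):
            paths = simple_paths(s, t)
            if not paths:
                continue
            d = min(len(p) for p in paths)
            geos = [p for p in paths if len(p) == d]
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in geos if v in p)
                raw[v] += through / len(geos)
    norm = raw / ((n - 1) * (n - 2) / 2)
    return raw, norm


def reachable_by_powering(edges: np.ndarray) -> bool:
    """Connectivity via transitive closure by boolean matrix powering."""
    n = edges.shape[0]
    reach = np.eye(n, dtype=bool) | edges.astype(bool)
    for _ in range(n):
        reach = reach | (reach @ reach)
    return bool(reach.all())


def tally_counts(incidence: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column and per-pair counts by explicit loops."""
    m, p = incidence.shape
    counts = np.zeros(p, dtype=int)
    co = np.zeros((p, p), dtype=int)
    for i in range(m):
        for x in range(p):
            if incidence[i, x]:
                counts[x] += 1
                for y in range(p):
                    if y != x and incidence[i, y]:
                        co[x, y] += 1
    return counts, co


def pointwise_mi(n_x: int, n_y: int, n_xy: int, m: int) -> float:
    """The association statistic, written out longhand."""
    if n_xy == 0:
        return 0.0
    import math

    p_xy = n_xy / m
    p_x = n_x / m
    p_y = n_y / m
    return p_xy * math.log(p_xy / (p_x * p_y))
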