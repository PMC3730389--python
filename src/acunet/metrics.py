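"""Centrality and modularity analysis of binarized acupoint networks.

Degree is the plain edge count of a node.  Betweenness is the fraction of
shortest paths between other node pairs that pass through a node (Brandes'
algorithm via networkx); the normalized form divides the raw unordered-pair
count by (p-1)(p-2)/2 so the middle node of a path graph scores exactly 1.

Modularity Q compares within-module edge mass to its degree-preserving random
expectation:

    Q = (1/2l) * sum_ij (a_ij - k_i k_j / 2l) delta_ij
      = sum_c ( e_c / l  -  (d_c / 2l)^2 ),

with l the edge count, e_c the edges inside module c and d_c its total degree.
Some sources print a 1/(4l) prefactor for the same double sum, which is
exactly half this value and does not change which partition maximizes Q; the
``quarter_prefactor`` flag reproduces that convention.

Module detection maximizes Q by greedy agglomeration from singletons followed
by Kernighan-Lin-style single-node refinement sweeps, with seeded restarts;
it is deterministic for a fixed (seed, restarts).  ``exact_best_partition``
is the exhaustive oracle for small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .binarize import AdjacencyMatrix, is_fully_connected

__all__ = [
    "CentralityTable",
    "Partition",
    "degree_centrality",
    "betweenness_centrality",
    "modularity_q",
    "detect_modules",
    "exact_best_partition",
]


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class CentralityTable:
    labels: tuple[str, ...]
    degree: tuple[int, ...]
    betweenness_raw: tuple[float, ...]
    betweenness_norm: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "acupoint": list(self.labels),
                "degree": list(self.degree),
                "betweenness_raw": list(self.betweenness_raw),
                "betweenness_norm": list(self.betweenness_norm),
            }
        )


@dataclass(frozen=True)
class Partition:
    """Module assignment per node plus its (standard-prefactor) Q."""

    labels: tuple[str, ...]
    assignment: tuple[int, ...]
    q: float

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.assignment):
            raise MetricsError("assignment length does not match labels")

    @property
    def module_count(self) -> int:
        return len(set(self.assignment))

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for lab, mod in zip(self.labels, self.assignment):
            out.setdefault(mod, []).append(lab)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"acupoint": list(self.labels), "module": list(self.assignment)}
        )


def _graph(adj: AdjacencyMatrix) -> nx.Graph:
    g = nx.from_numpy_array(adj.edges)
    return nx.relabel_nodes(g, dict(enumerate(adj.labels)))


def degree_centrality(adj: AdjacencyMatrix) -> tuple[int, ...]:
    """Per-node edge counts (row sums), in label order."""
    return tuple(int(d) for d in adj.edges.sum(axis=1))


def betweenness_centrality(adj: AdjacencyMatrix) -> CentralityTable:
    """Brandes betweenness, raw and normalized by (p-1)(p-2)/2."""
    if adj.p < 3:
        raise MetricsError("betweenness normalization needs p >= 3")
    g = _graph(adj)
    raw = nx.betweenness_centrality(g, normalized=False)
    norm = nx.betweenness_centrality(g, normalized=True)
    return CentralityTable(
        labels=adj.labels,
        degree=degree_centrality(adj),
        betweenness_raw=tuple(raw[lab] for lab in adj.labels),
        betweenness_norm=tuple(norm[lab] for lab in adj.labels),
    )


def _q_from_aggregates(adj: AdjacencyMatrix, assignment: Sequence[int]) -> float:
    edges = adj.edges
    degrees = edges.sum(axis=1).astype(float)
    l = degrees.sum() / 2
    labels = np.asarray(assignment)
    q = 0.0
    for mod in np.unique(labels):
        mask = labels == mod
        e_c = edges[np.ix_(mask, mask)].sum() / 2
        d_c = degrees[mask].sum()
        q += e_c / l - (d_c / (2 * l)) ** 2
    return float(q)


def modularity_q(
    adj: AdjacencyMatrix,
    assignment: Sequence[int],
    quarter_prefactor: bool = False,
) -> float:
    """Newman-Girvan modularity of a full node-to-module assignment.

    With ``quarter_prefactor=True`` the 1/(4l) convention is used, giving
    exactly half the standard value.
    """
    if len(assignment) != adj.p:
        raise MetricsError("assignment must cover every node")
    if adj.edge_count == 0:
        raise MetricsError("modularity undefined on a zero-edge graph")
    q = _q_from_aggregates(adj, assignment)
    return q / 2 if quarter_prefactor else q


class _Agglomerator:
    """Greedy Q-maximizing merges + single-node refinement on one graph."""

    def __init__(self, adj: AdjacencyMatrix):
        self.n = adj.p
        self.a = adj.edges.astype(float)
        self.k = self.a.sum(axis=1)
        self.two_l = self.k.sum()

    def run(self, rng: np.random.Generator | None) -> np.ndarray:
        comm = np.arange(self.n)
        # alternate greedy merging with node-level refinement until Q settles
        for _ in range(20):
            merged = self._merge(comm, rng)
            refined = self._refine(merged, rng)
            if np.array_equal(refined, comm):
                break
            comm = refined
        return comm

    def _merge(self, comm: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        """Greedily merge whole communities while any merge improves Q."""
        n = self.n
        two_l = self.two_l
        comm = comm.copy()
        # community-level aggregates, indexed by community id
        e = np.zeros((n, n))
        d = np.zeros(n)
        alive = np.zeros(n, dtype=bool)
        for v in range(n):
            d[comm[v]] += self.k[v]
            alive[comm[v]] = True
            for u in range(n):
                e[comm[v], comm[u]] += self.a[v, u]
        while alive.sum() > 1:
            idx = np.flatnonzero(alive)
            # delta Q of merging c1, c2: 2*(e12/2l - d1*d2/(2l)^2)
            e_sub = e[np.ix_(idx, idx)]
            d_sub = d[idx]
            gain = 2 * (e_sub / two_l - np.outer(d_sub, d_sub) / two_l**2)
            np.fill_diagonal(gain, -np.inf)
            best = float(gain.max())
            if best <= 1e-12:
                break
            cands = np.argwhere(gain >= best - 1e-12)
            pick = 0 if rng is None else int(rng.integers(len(cands)))
            i, j = cands[pick]
            c1, c2 = int(idx[i]), int(idx[j])
            if c2 < c1:
                c1, c2 = c2, c1
            comm[comm == c2] = c1
            e[c1, :] += e[c2, :]
            e[:, c1] += e[:, c2]
            d[c1] += d[c2]
            alive[c2] = False
        return comm

    def _refine(self, comm: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        """Single-node moves: to any community, or out into a new singleton."""
        n = self.n
        two_l = self.two_l
        comm = comm.copy()
        improved = True
        sweeps = 0
        while improved and sweeps < 50:
            improved = False
            sweeps += 1
            order = np.arange(n)
            if rng is not None:
                rng.shuffle(order)
            for v in order:
                cur = comm[v]
                # edge mass from v into each community (excluding v itself)
                mass = np.zeros(n)
                for u in np.flatnonzero(self.a[v] > 0):
                    if u != v:
                        mass[comm[u]] += self.a[v, u]
                d_comm = np.zeros(n)
                for c in np.unique(comm):
                    d_comm[c] = self.k[comm == c].sum()
                kv = self.k[v]
                # Q change of moving v from cur to c
                base = mass[cur] - kv * (d_comm[cur] - kv) / two_l
                best_c, best_gain = cur, 0.0
                targets = [int(c) for c in np.unique(comm) if c != cur]
                if (comm == cur).sum() > 1:
                    # leaving into a brand-new singleton community
                    fresh = next(c for c in range(n) if c not in comm)
                    targets.append(fresh)
                for c in targets:
                    gain = (mass[c] - kv * d_comm[c] / two_l) - base
                    if gain > best_gain + 1e-12 or (
                        gain > best_gain - 1e-12 and gain > 1e-12 and c < best_c
                    ):
                        best_c, best_gain = int(c), float(gain)
                if best_c != cur:
                    comm[v] = best_c
                    improved = True
        return comm


def _canonical(assignment: Sequence[int]) -> tuple[int, ...]:
    """Relabel module ids in first-appearance order (restricted growth form)."""
    seen: dict[int, int] = {}
    out = []
    for a in assignment:
        if a not in seen:
            seen[a] = len(seen)
        out.append(seen[a])
    return tuple(out)


def detect_modules(
    adj: AdjacencyMatrix, seed: int = 0, restarts: int = 10
) -> Partition:
    """Locally Q-optimal partition; best of ``restarts`` seeded runs.

    Run 0 is fully deterministic (first-index tie-breaks); later runs perturb
    merge tie-breaks and refinement order.  Deterministic for fixed
    (seed, restarts).
    """
    if restarts < 1:
        raise MetricsError("restarts must be >= 1")
    if adj.edge_count == 0:
        raise MetricsError("cannot detect modules on a zero-edge graph")
    if not is_fully_connected(adj):
        import warnings

        warnings.warn("graph is not connected; modules will split components")
    agg = _Agglomerator(adj)
    best: tuple[float, tuple[int, ...]] | None = None
    for r in range(restarts):
        rng = None if r == 0 else np.random.default_rng((seed, r))
        comm = _canonical(agg.run(rng))
        q = modularity_q(adj, comm)
        if best is None or q > best[0] + 1e-12 or (abs(q - best[0]) <= 1e-12 and comm < best[1]):
            best = (q, comm)
    assert best is not None
    return Partition(labels=adj.labels, assignment=best[1], q=best[0])


def _set_partitions(n: int) -> Iterator[tuple[int, ...]]:
    """All set partitions of range(n) as restricted-growth strings."""
    a = [0] * n
    b = [0] * n  # b[i] = max(a[:i+1])

    def rec(i: int) -> Iterator[tuple[int, ...]]:
        if i == n:
            yield tuple(a)
            return
        top = b[i - 1] if i > 0 else -1
        for v in range(top + 2):
            a[i] = v
            b[i] = max(top, v)
            yield from rec(i + 1)

    yield from rec(0)


def exact_best_partition(adj: AdjacencyMatrix, max_nodes: int = 12) -> Partition:
    """Exhaustive maximum-Q partition (oracle); refuses p > ``max_nodes``.

    Ties resolve to the lexicographically smallest restricted-growth
    assignment.
    """
    if adj.p > max_nodes:
        raise MetricsError(f"exhaustive search refused for p > {max_nodes}")
    if adj.edge_count == 0:
        raise MetricsError("modularity undefined on a zero-edge graph")
    edges = adj.edge_set()
    degrees = adj.edges.sum(axis=1).astype(float)
    l = degrees.sum() / 2
    best_q = -np.inf
    best_assign: tuple[int, ...] | None = None
    for assign in _set_partitions(adj.p):
        n_mod = max(assign) + 1
        e_c = [0.0] * n_mod
        d_c = [0.0] * n_mod
        for i, j in edges:
            if assign[i] == assign[j]:
                e_c[assign[i]] += 1.0
        for v in range(adj.p):
            d_c[assign[v]] += degrees[v]
        q = sum(e / l - (d / (2 * l)) ** 2 for e, d in zip(e_c, d_c))
        if q > best_q + 1e-12:
            best_q, best_assign = q, assign
    assert best_assign is not None
    return Partition(labels=adj.labels, assignment=best_assign, q=float(best_q))
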