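"""Thresholding the MI matrix into binary networks and scanning thresholds.

A threshold R turns the weighted MI matrix into an unweighted graph: an edge
joins two acupoints iff their MI value strictly exceeds R.  Scanning R over a
fine grid trades spurious weak edges against fragmentation; the scan records,
per R, the edge count, the edge density E / (p(p-1)/2) and whether the graph
is still a single connected component, and identifies the largest grid R that
keeps the network fully connected.  Analysis networks are then selected by an
edge-density band, keeping only strong edges while preserving connectivity.

Grid values are carried as integer thousandths so that thresholds like 0.022
are exact and sortable without floating-point drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .mi import MIMatrix

__all__ = [
    "AdjacencyMatrix",
    "ThresholdScanResult",
    "default_grid",
    "binarize",
    "edge_density",
    "is_fully_connected",
    "scan_thresholds",
    "select_by_density",
]


class BinarizeError(ValueError):
    pass


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary, symmetric, zero-diagonal adjacency over labelled acupoints."""

    labels: tuple[str, ...]
    edges: np.ndarray = field(repr=False)
    threshold: float | None = None  # R that produced this network, if any

    def __post_init__(self) -> None:
        e = np.asarray(self.edges)
        if e.shape != (len(self.labels), len(self.labels)):
            raise BinarizeError("edges shape does not match labels")
        if not np.isin(e, (0, 1)).all():
            raise BinarizeError("edges must be 0/1")
        if not np.array_equal(e, e.T):
            raise BinarizeError("edges must be symmetric")
        if np.any(np.diag(e) != 0):
            raise BinarizeError("diagonal must be zero")
        e = e.astype(np.uint8)
        e.setflags(write=False)
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def p(self) -> int:
        return len(self.labels)

    @property
    def edge_count(self) -> int:
        return int(self.edges.sum()) // 2

    def edge_set(self) -> frozenset[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.edges, k=1))
        return frozenset(zip(ii.tolist(), jj.tolist()))

    def edge_list(self) -> list[tuple[str, str]]:
        return [(self.labels[i], self.labels[j]) for i, j in sorted(self.edge_set())]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.edges.astype(int), index=list(self.labels), columns=list(self.labels)
        )


@dataclass(frozen=True)
class ThresholdScanResult:
    """Per-threshold record of the binarization scan.

    ``r_max_connected`` is the largest grid R whose network is a single
    connected component, or ``None`` when no grid R yields one.
    """

    grid_milli: tuple[int, ...]
    edge_counts: tuple[int, ...]
    densities: tuple[float, ...]
    connected: tuple[bool, ...]
    r_max_connected: float | None

    @property
    def grid(self) -> tuple[float, ...]:
        return tuple(r / 1000 for r in self.grid_milli)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": [f"{r / 1000:.3f}" for r in self.grid_milli],
                "edge_count": self.edge_counts,
                "edge_density": self.densities,
                "fully_connected": [int(c) for c in self.connected],
            }
        )


def default_grid() -> tuple[int, ...]:
    """The standard scan grid, 0.001..0.999 in 0.001 steps, as thousandths."""
    return tuple(range(1, 1000))


def _as_milli(grid: Sequence[int] | Sequence[float] | None) -> tuple[int, ...]:
    if grid is None:
        return default_grid()
    milli = []
    for r in grid:
        v = int(round(float(r) * 1000)) if not isinstance(r, (int, np.integer)) else int(r)
        milli.append(v)
    if not milli:
        raise BinarizeError("grid is empty")
    if any(b <= a for a, b in zip(milli, milli[1:])):
        raise BinarizeError("grid must be strictly increasing")
    return tuple(milli)


def binarize(mi: MIMatrix, r: float) -> AdjacencyMatrix:
    """Edge iff MI strictly greater than r ("exceeding the threshold")."""
    if not np.isfinite(r):
        raise BinarizeError("threshold must be finite")
    edges = (mi.values > r).astype(np.uint8)
    np.fill_diagonal(edges, 0)
    return AdjacencyMatrix(labels=mi.labels, edges=edges, threshold=float(r))


def edge_density(adj: AdjacencyMatrix) -> float:
    """Realized undirected edges over the p(p-1)/2 possible."""
    if adj.p < 2:
        raise BinarizeError("edge density needs p >= 2")
    return adj.edge_count / (adj.p * (adj.p - 1) / 2)


def is_fully_connected(adj: AdjacencyMatrix) -> bool:
    """True iff the graph is a single connected component.

    "Fully connected" here means graph connectivity (no fragments), not a
    complete graph.
    """
    if adj.p == 1:
        return True
    n_comp, _ = connected_components(csr_matrix(adj.edges), directed=False)
    return bool(n_comp == 1)


def scan_thresholds(
    mi: MIMatrix, grid: Sequence[float] | Sequence[int] | None = None
) -> ThresholdScanResult:
    """Binarize at every grid R; record edges, density, connectivity.

    Grid values may be floats (rounded to thousandths) or integer thousandths.
    """
    milli = _as_milli(grid)
    n_pairs = mi.p * (mi.p - 1) / 2
    counts, dens, conn = [], [], []
    for r in milli:
        adj = binarize(mi, r / 1000)
        e = adj.edge_count
        counts.append(e)
        dens.append(e / n_pairs)
        conn.append(is_fully_connected(adj))
    r_max = None
    for r, c in zip(milli, conn):
        if c:
            r_max = r / 1000
    return ThresholdScanResult(
        grid_milli=milli,
        edge_counts=tuple(counts),
        densities=tuple(dens),
        connected=tuple(conn),
        r_max_connected=r_max,
    )


def select_by_density(
    mi: MIMatrix,
    density_lo: float,
    density_hi: float,
    grid: Sequence[float] | Sequence[int] | None = None,
) -> list[AdjacencyMatrix]:
    """Connected grid networks whose density falls in [lo, hi], sparsest first.

    Returns the binarized networks along the grid whose edge density lies in
    the band *and* that remain a single component, ordered by decreasing R
    (so the first element is the sparsest admissible network).  Consecutive
    grid values that produce the identical network are collapsed to the
    largest R.
    """
    if not 0 < density_lo <= density_hi <= 1:
        raise BinarizeError("need 0 < density_lo <= density_hi <= 1")
    scan = scan_thresholds(mi, grid)
    out: list[AdjacencyMatrix] = []
    seen_counts: set[int] = set()
    for r_milli, dens, conn, cnt in sorted(
        zip(scan.grid_milli, scan.densities, scan.connected, scan.edge_counts),
        reverse=True,
    ):
        if conn and density_lo <= dens <= density_hi and cnt not in seen_counts:
            out.append(binarize(mi, r_milli / 1000))
            seen_counts.add(cnt)
    if not out:
        raise BinarizeError(
            f"no connected network with density in [{density_lo}, {density_hi}]; "
            "widen the band"
        )
    return out


def nearest_to_density(
    networks: Sequence[AdjacencyMatrix], target: float
) -> AdjacencyMatrix:
    """The network whose density is closest to ``target``; ties -> larger R."""
    if not networks:
        raise BinarizeError("no candidate networks")
    return min(
        networks,
        key=lambda a: (abs(edge_density(a) - target), -(a.threshold or 0.0)),
    )
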