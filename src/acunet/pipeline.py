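"""End-to-end orchestration: incidence -> MI -> binarize -> metrics -> report.

`run_pipeline` chains frequency filtering, MI-matrix construction, the
threshold scan, density-band network selection, centrality and module
detection, and writes every intermediate artifact (CSV/TSV/GraphML plus a
JSON run manifest) to an output directory.  The report tables mirror the
conventional presentation of such analyses: a per-acupoint usage table
(rank, frequency %, degree, betweenness) and a high-MI pair table tagged
local (L) when both members lie in a configured local-region set, else
distant (D).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .binarize import (
    AdjacencyMatrix,
    ThresholdScanResult,
    edge_density,
    nearest_to_density,
    scan_thresholds,
    select_by_density,
)
from .incidence import (
    PrescriptionDataset,
    filter_by_frequency,
    load_incidence,
    percent,
    usage_stats,
    write_incidence,
)
from .metrics import (
    CentralityTable,
    Partition,
    betweenness_centrality,
    detect_modules,
)
from .mi import MIMatrix, mi_matrix
from .synthetic import LOCAL_ACUPOINTS

log = logging.getLogger("acunet")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "tag_pairs", "export_graphml"]


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full analysis.

    ``min_freq`` is the strict usage-frequency cut for including an acupoint;
    the density band and target pick the analysis network among connected
    thresholded graphs; ``mi_cut`` is the floor for the high-MI pair report.
    """

    input_path: str | Path | None = None
    min_freq: float = 0.05
    density_lo: float = 0.39
    density_hi: float = 0.50
    target_density: float = 0.40
    mi_cut: float = 0.17
    seed: int = 0
    restarts: int = 10
    local_set: frozenset[str] = LOCAL_ACUPOINTS
    out_dir: str | Path | None = None
    mi_decimals: int = 4
    freq_decimals: int = 1
    betweenness_decimals: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.density_lo <= self.density_hi <= 1:
            raise PipelineError("invalid density band")
        for p in (self.mi_decimals, self.freq_decimals, self.betweenness_decimals):
            if p < 0:
                raise PipelineError("precisions must be >= 0")


@dataclass(frozen=True)
class ReportBundle:
    """All products of one pipeline run."""

    dataset: PrescriptionDataset
    mi: MIMatrix
    scan: ThresholdScanResult
    network: AdjacencyMatrix
    centrality: CentralityTable
    partition: Partition
    usage_table: pd.DataFrame
    pair_table: pd.DataFrame
    manifest: dict = field(repr=False)


def tag_pairs(
    pairs: pd.DataFrame,
    local_set: Iterable[str],
    known_labels: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Add a local/distant tag column: L iff both members are local.

    ``pairs`` needs columns ``acupoint_a`` and ``acupoint_b``.  When
    ``known_labels`` is given, a pair member outside it raises.
    """
    local = frozenset(local_set)
    if known_labels is not None:
        known = set(known_labels)
        unknown = (set(pairs["acupoint_a"]) | set(pairs["acupoint_b"])) - known
        if unknown:
            raise PipelineError(f"unknown acupoint labels in pair table: {sorted(unknown)}")
    out = pairs.copy()
    out["tag"] = [
        "L" if a in local and b in local else "D"
        for a, b in zip(out["acupoint_a"], out["acupoint_b"])
    ]
    return out


def export_graphml(
    adj: AdjacencyMatrix,
    node_attrs: Mapping[str, Mapping[str, object]] | None,
    path: str | Path,
) -> Path:
    """Write an undirected GraphML file with per-node attribute maps.

    ``node_attrs`` maps attribute name -> {label: value}.  Re-parsing the file
    round-trips node and edge sets.
    """
    g = nx.Graph()
    g.add_nodes_from(adj.labels)
    g.add_edges_from(adj.edge_list())
    for attr, mapping in (node_attrs or {}).items():
        nx.set_node_attributes(g, dict(mapping), attr)
    path = Path(path)
    nx.write_graphml(g, path, named_key_ids=True)
    return path


def _inband_ignoring_connectivity(
    mi: MIMatrix, scan: ThresholdScanResult, config: PipelineConfig
) -> list[AdjacencyMatrix]:
    from .binarize import binarize

    out: list[AdjacencyMatrix] = []
    seen: set[int] = set()
    for r_milli, dens, cnt in sorted(
        zip(scan.grid_milli, scan.densities, scan.edge_counts), reverse=True
    ):
        if config.density_lo <= dens <= config.density_hi and cnt not in seen:
            out.append(binarize(mi, r_milli / 1000))
            seen.add(cnt)
    return out


def _resolve_input(config: PipelineConfig) -> PrescriptionDataset:
    if isinstance(config.input_path, PrescriptionDataset):
        return config.input_path
    if config.input_path is None:
        from .synthetic import lbp_fixture

        return lbp_fixture()
    return load_incidence(config.input_path)


def _usage_table(
    ds: PrescriptionDataset,
    centrality: CentralityTable,
    config: PipelineConfig,
) -> pd.DataFrame:
    stats = usage_stats(ds)
    bet = dict(zip(centrality.labels, centrality.betweenness_norm))
    deg = dict(zip(centrality.labels, centrality.degree))
    df = pd.DataFrame(
        {
            "acupoint": list(ds.acupoint_labels),
            "frequency_pct": [percent(int(n), ds.m) for n in stats.counts],
            "degree": [deg[a] for a in ds.acupoint_labels],
            "betweenness": [
                round(bet[a], config.betweenness_decimals)
                for a in ds.acupoint_labels
            ],
        }
    )
    df = df.sort_values(
        ["frequency_pct", "acupoint"], ascending=[False, True]
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


def _pair_table(mi: MIMatrix, config: PipelineConfig) -> pd.DataFrame:
    long = mi.to_long()
    long["mi"] = long["mi"].round(config.mi_decimals)
    sel = long[long["mi"] > config.mi_cut].copy()
    sel = sel.sort_values(
        ["mi", "acupoint_a", "acupoint_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return tag_pairs(sel, config.local_set, known_labels=mi.labels)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis; write artifacts when ``out_dir`` is set.

    Stages: frequency filter -> MI matrix -> threshold scan -> density-band
    selection (analysis network = density nearest ``target_density``, ties to
    the larger threshold) -> centralities -> module detection.  Deterministic
    for a fixed config and seed.
    """
    ds = _resolve_input(config)
    log.info("input: %d studies x %d acupoints", ds.m, ds.p)
    try:
        ds = filter_by_frequency(ds, config.min_freq)
    except Exception as exc:
        raise PipelineError(f"frequency filter: {exc}") from exc
    log.info("retained %d acupoints above frequency %.3f", ds.p, config.min_freq)

    mi = mi_matrix(ds)
    scan = scan_thresholds(mi)
    log.info("threshold scan: r_max_connected=%s", scan.r_max_connected)
    try:
        candidates = select_by_density(mi, config.density_lo, config.density_hi)
    except Exception as exc:
        # strongly modular data can have no connected network at any positive
        # threshold (all between-module association below independence); fall
        # back to in-band selection by density alone and analyze components
        candidates = _inband_ignoring_connectivity(mi, scan, config)
        if not candidates:
            raise PipelineError(
                f"density selection: {exc} "
                f"(band [{config.density_lo}, {config.density_hi}])"
            ) from exc
        log.warning(
            "no connected network in density band; using disconnected "
            "networks (modules will follow components)"
        )
    network = nearest_to_density(candidates, config.target_density)
    log.info(
        "analysis network: R=%s, density=%.4f, %d edges",
        network.threshold,
        edge_density(network),
        network.edge_count,
    )
    centrality = betweenness_centrality(network)
    partition = detect_modules(network, seed=config.seed, restarts=config.restarts)
    log.info("partition: %d modules, Q=%.4f", partition.module_count, partition.q)

    usage = _usage_table(ds, centrality, config)
    pairs = _pair_table(mi, config)
    manifest = {
        "acunet_version": __version__,
        "seed": config.seed,
        "restarts": config.restarts,
        "m": ds.m,
        "p": ds.p,
        "min_freq": config.min_freq,
        "grid": "0.001..0.999 step 0.001",
        "r_max_connected": scan.r_max_connected,
        "analysis_r": network.threshold,
        "analysis_density": edge_density(network),
        "analysis_edges": network.edge_count,
        "modularity_q": partition.q,
        "module_count": partition.module_count,
        "mi_cut": config.mi_cut,
        "density_band": [config.density_lo, config.density_hi],
        "target_density": config.target_density,
    }
    bundle = ReportBundle(
        dataset=ds,
        mi=mi,
        scan=scan,
        network=network,
        centrality=centrality,
        partition=partition,
        usage_table=usage,
        pair_table=pairs,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir), config)
    return bundle


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def _write_bundle(bundle: ReportBundle, out: Path, config: PipelineConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_incidence(bundle.dataset, out / "incidence.csv")
    bundle.mi.to_frame().to_csv(out / "mi_matrix.csv", lineterminator="\n")
    bundle.mi.to_long().to_csv(
        out / "mi_pairs.tsv", sep="\t", index=False, lineterminator="\n"
    )
    _write_csv(bundle.scan.to_frame(), out / "threshold_scan.csv")
    bundle.network.to_frame().to_csv(out / "adjacency.csv", lineterminator="\n")
    pd.DataFrame(bundle.network.edge_list(), columns=["acupoint_a", "acupoint_b"]).to_csv(
        out / "edges.tsv", sep="\t", index=False, lineterminator="\n"
    )
    cent = bundle.centrality.to_frame()
    cent["module"] = list(bundle.partition.assignment)
    _write_csv(cent, out / "centrality.csv")
    _write_csv(bundle.usage_table, out / "usage_table.csv")
    _write_csv(bundle.pair_table, out / "pair_table.csv")
    _write_csv(bundle.partition.to_frame(), out / "partition.csv")
    export_graphml(
        bundle.network,
        {
            "degree": dict(zip(bundle.centrality.labels, bundle.centrality.degree)),
            "betweenness": dict(
                zip(bundle.centrality.labels, bundle.centrality.betweenness_norm)
            ),
            "module": dict(zip(bundle.partition.labels, bundle.partition.assignment)),
        },
        out / "network.graphml",
    )
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n"
    )
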