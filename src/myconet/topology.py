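"""Network topology: module detection, global metrics, per-sample subgraphs.

Community detection runs on the unweighted, unsigned graph (signed
modularity is out of scope).  Average path length is the mean shortest-path
length over *connected* pairs only, a deliberate convention because the
per-sample induced subgraphs are frequently disconnected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import networkx as nx
import pandas as pd

from .core import AsvTable, CooccurrenceNetwork, ModulePartition, ValidationError

__all__ = [
    "detect_modules",
    "GlobalMetrics",
    "global_metrics",
    "sample_subnetwork",
    "subnetwork_metrics_all",
    "habitat_summary",
]

SUBNETWORK_COLUMNS = [
    "sample_id",
    "node_count",
    "edge_count",
    "average_degree",
    "average_path_length",
    "global_clustering",
    "modularity",
]


def _unweighted_copy(net: CooccurrenceNetwork) -> nx.Graph:
    """Unweighted, unsigned copy with nodes/edges added in sorted order so
    community detection is reproducible."""
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes))
    g.add_edges_from(sorted(tuple(sorted(e)) for e in net.graph.edges))
    return g


def detect_modules(
    net: CooccurrenceNetwork, seed: int = 0, method: str = "greedy"
) -> ModulePartition:
    """Partition the network into modules by modularity maximization.

    ``method="greedy"`` (default) uses Clauset-Newman-Moore agglomeration,
    which is deterministic on the sorted graph; ``method="louvain"`` is
    available behind the flag and is deterministic given ``seed``.  Module
    ids are small integers ordered by each module's smallest node id.
    """
    if net.n_edges == 0:
        raise ValidationError("cannot detect modules in an edgeless network")
    g = _unweighted_copy(net)
    if method == "greedy":
        communities = nx.community.greedy_modularity_communities(g, weight=None)
    elif method == "louvain":
        communities = nx.community.louvain_communities(g, weight=None, seed=seed)
    else:
        raise ValidationError(f"unknown module detection method {method!r}")
    communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
    membership = {
        node: idx for idx, comm in enumerate(communities) for node in comm
    }
    q = nx.community.modularity(g, [set(c) for c in communities], weight=None)
    if not -0.5 - 1e-9 <= q <= 1.0 + 1e-9:  # pragma: no cover - defensive
        raise AssertionError(f"modularity {q} outside [-0.5, 1]")
    return ModulePartition(membership=membership, modularity=q)


@dataclass
class GlobalMetrics:
    node_count: int
    edge_count: int
    average_degree: float
    average_path_length: float  # NaN when no connected pair exists
    global_clustering: float  # transitivity; NaN when no connected triple
    modularity: float  # NaN when no partition supplied

    def as_dict(self) -> Dict[str, float]:
        return {
            "node_count": self.node_count,
            "edge_count": self.edge_count,
            "average_degree": self.average_degree,
            "average_path_length": self.average_path_length,
            "global_clustering": self.global_clustering,
            "modularity": self.modularity,
        }


def _average_path_length_connected_pairs(g: nx.Graph) -> float:
    total = 0
    pairs = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            total += sum(lengths.values())
            pairs += len(lengths) - 1  # exclude self
    if pairs == 0:
        return float("nan")
    return total / pairs  # each unordered pair counted twice in both sums


def global_metrics(
    net: CooccurrenceNetwork, partition: Optional[ModulePartition] = None
) -> GlobalMetrics:
    """Node/edge counts, mean degree (2E/N), connected-pairs average path
    length, transitivity, and (if a partition is given) its modularity."""
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return GlobalMetrics(0, 0, float("nan"), float("nan"), float("nan"),
                             float("nan"))
    avg_degree = 2.0 * e / n
    apl = _average_path_length_connected_pairs(g) if e else float("nan")
    triples = sum(d * (d - 1) for _, d in g.degree) / 2
    clustering = nx.transitivity(g) if triples else float("nan")
    modularity = partition.modularity if partition is not None else float("nan")
    return GlobalMetrics(n, e, avg_degree, apl, clustering, modularity)


def sample_subnetwork(
    net: CooccurrenceNetwork, table: AsvTable, sample_id: str
) -> CooccurrenceNetwork:
    """Induced subgraph of the taxa present (count > 0) in one sample."""
    if sample_id not in table.counts.index:
        raise ValidationError(f"unknown sample {sample_id!r}")
    row = table.counts.loc[sample_id]
    present = set(row.index[row > 0])
    return net.induced_subgraph(present)


def subnetwork_metrics_all(
    net: CooccurrenceNetwork,
    table: AsvTable,
    detect_sub_modules: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Topological metrics of every sample's induced subnetwork.

    Metrics of an empty subnetwork are NaN (undefined), never zero-filled.
    """
    rows = []
    for sample_id in table.sample_ids:
        sub = sample_subnetwork(net, table, sample_id)
        partition = None
        if detect_sub_modules and sub.n_edges > 0:
            partition = detect_modules(sub, seed=seed)
        gm = global_metrics(sub, partition)
        rows.append({"sample_id": sample_id, **gm.as_dict()})
    return pd.DataFrame(rows, columns=SUBNETWORK_COLUMNS)


def habitat_summary(
    metrics: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Per-habitat means of the per-sample subnetwork metrics."""
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    joined = metrics.join(meta["habitat"], on="sample_id")
    return (
        joined.groupby("habitat", sort=True)[SUBNETWORK_COLUMNS[1:]]
        .mean()
        .reset_index()
    )
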