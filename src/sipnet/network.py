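"""Co-occurrence network inference from OTU repartition profiles.

The network connects OTUs whose across-sample repartition patterns are
similar: OTUs are prevalence-filtered (> 25% of samples by default), each
OTU's profile is normalized to proportions across samples (so absolute
abundance is irrelevant, only where reads fall), and an undirected edge
joins every OTU pair whose Bray–Curtis dissimilarity is at most the
threshold (0.12 by default — small distance = strong co-occurrence).

Each node carries two preference coordinates in [−1, 1]:

    x = (%E − %C) / (%E + %C)   plant strategy: exploitative vs conservative
    y = (%H − %L) / (%H + %L)   carbon source: heavy (¹³C exudates) vs light (SOM)

where %E, %C, %H, %L are the OTU's mean per-sample relative abundances
within each sample class. Using class means rather than pooled read
counts keeps a preference-free OTU at 0 even when the classes hold
unequal numbers of samples (the study design has 4 exploitative vs 2
conservative species); with balanced classes and equal depths the two
readings coincide. A coordinate is undefined (None) when the OTU has no
reads in either class of the pair; the node is retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .otu import OtuTable, prevalence_filter, to_proportions

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.12
DEFAULT_MIN_PREVALENCE = 0.25


@dataclass(frozen=True)
class NodePosition:
    """Preference coordinates of one OTU; None marks an undefined axis."""

    x: float | None
    y: float | None

    def __post_init__(self) -> None:
        for v in (self.x, self.y):
            if v is not None and abs(v) > 1 + 1e-12:
                raise ValueError(f"coordinate {v} outside [-1, 1]")


@dataclass
class CooccurrenceNetwork:
    """Undirected OTU co-occurrence graph.

    ``nodes`` maps otu_id -> (phylum, NodePosition); ``edges`` lists each
    unordered pair once with its Bray–Curtis dissimilarity (every edge
    dissimilarity ≤ ``threshold``; no self-edges).
    """

    nodes: dict[str, tuple[str, NodePosition]]
    edges: list[tuple[str, str, float]]
    threshold: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(threshold=self.threshold, provenance=json.dumps(self.provenance, sort_keys=True))
        for otu_id, (phylum, pos) in self.nodes.items():
            attrs: dict = {"phylum": phylum}
            if pos.x is not None:
                attrs["x"] = float(pos.x)
            if pos.y is not None:
                attrs["y"] = float(pos.y)
            g.add_node(otu_id, **attrs)
        for a, b, d in self.edges:
            g.add_edge(a, b, dissimilarity=float(d))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "CooccurrenceNetwork":
        nodes = {}
        for n, attrs in g.nodes(data=True):
            pos = NodePosition(x=attrs.get("x"), y=attrs.get("y"))
            nodes[n] = (attrs.get("phylum", "unclassified"), pos)
        edges = sorted(
            (min(a, b), max(a, b), float(attrs["dissimilarity"]))
            for a, b, attrs in g.edges(data=True)
        )
        provenance = json.loads(g.graph.get("provenance", "{}"))
        return cls(
            nodes=nodes,
            edges=edges,
            threshold=float(g.graph.get("threshold", DEFAULT_THRESHOLD)),
            provenance=provenance,
        )


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    mean_degree: float
    clustering_coefficient: float
    characteristic_path_length: float
    n_disconnected_pairs: int = 0


def node_positions(
    table: OtuTable, otus: Sequence[str] | None = None
) -> dict[str, NodePosition]:
    """Strategy (x) and carbon-source (y) preference coordinates per OTU."""
    otus = list(otus) if otus is not None else table.otu_ids
    rel = table.counts.div(table.counts.sum(axis=1).replace(0, np.nan), axis=0)

    def class_mean(ids: list[str]) -> pd.Series:
        if not ids:
            return pd.Series(0.0, index=table.counts.columns)
        return rel.loc[ids].mean(axis=0).fillna(0.0)

    E = class_mean(table.samples_where(strategy="exploitative"))
    C = class_mean(table.samples_where(strategy="conservative"))
    H = class_mean(table.samples_where(compartment="heavy"))
    L = class_mean(table.samples_where(compartment="light"))

    out: dict[str, NodePosition] = {}
    for otu in otus:
        e, c, h, l = E[otu], C[otu], H[otu], L[otu]
        x = None if e + c == 0 else float((e - c) / (e + c))
        y = None if h + l == 0 else float((h - l) / (h + l))
        out[otu] = NodePosition(x=x, y=y)
    return out


def build_network(
    table: OtuTable,
    min_prevalence: float = DEFAULT_MIN_PREVALENCE,
    threshold: float = DEFAULT_THRESHOLD,
    compartments: Sequence[str] | None = None,
    normalization: Literal["per_otu", "per_sample"] = "per_otu",
    edge_rule: Literal["dissimilarity_le", "similarity_ge"] = "dissimilarity_le",
    position_table: OtuTable | None = None,
) -> CooccurrenceNetwork:
    """Infer the co-occurrence network from an OTU table.

    Stages: optional compartment restriction → prevalence filter →
    per-OTU proportion profiles → all-pairs Bray–Curtis → threshold rule.
    ``edge_rule`` selects whether 0.12 bounds the dissimilarity (default:
    d ≤ threshold) or the similarity (1 − d ≥ threshold).
    ``position_table`` lets preference coordinates be computed on a wider
    table (e.g. including both fractions) than the one edges are built
    from; it defaults to the restricted table.
    """
    work = table
    if compartments is not None:
        work = table.subset_samples(table.samples_where(compartment=set(compartments)))
    if work.n_samples < 2:
        raise ValueError("network inference needs at least 2 samples")
    filtered = prevalence_filter(work, min_prevalence=min_prevalence)
    provenance = {
        "min_prevalence": min_prevalence,
        "threshold": threshold,
        "normalization": normalization,
        "edge_rule": edge_rule,
        "compartments": sorted(compartments) if compartments is not None else None,
        "n_samples": filtered.n_samples,
    }
    phylum = filtered.rank_labels("phylum")
    positions = node_positions(position_table or filtered, filtered.otu_ids)
    if filtered.n_otus == 0:
        logger.warning("no OTUs survive the prevalence filter; empty network")
        return CooccurrenceNetwork(nodes={}, edges=[], threshold=threshold, provenance=provenance)
    nodes = {otu: (phylum[otu], positions[otu]) for otu in filtered.otu_ids}
    if filtered.n_otus == 1:
        return CooccurrenceNetwork(nodes=nodes, edges=[], threshold=threshold, provenance=provenance)
    profiles = to_proportions(filtered, normalization)
    if normalization == "per_otu":
        profiles = profiles.T  # OTUs in rows: compare repartition patterns
    otu_ids = list(profiles.index)
    dm = squareform(pdist(profiles.to_numpy(dtype=float), metric="braycurtis"))
    edges: list[tuple[str, str, float]] = []
    n = len(otu_ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(dm[i, j])
            keep = d <= threshold if edge_rule == "dissimilarity_le" else (1 - d) >= threshold
            if keep:
                a, b = sorted((otu_ids[i], otu_ids[j]))
                edges.append((a, b, d))
    edges.sort()
    return CooccurrenceNetwork(nodes=nodes, edges=edges, threshold=threshold, provenance=provenance)


def network_stats(
    net: CooccurrenceNetwork | nx.Graph,
    count_low_degree_as_zero: bool = True,
) -> NetworkStats:
    """Global graph statistics: mean degree, clustering, path length.

    ``mean_degree`` is exactly 2E/N. The clustering coefficient averages
    local transitivity over all nodes, with degree-< 2 nodes contributing
    0 (set ``count_low_degree_as_zero=False`` to exclude them instead).
    The characteristic path length averages shortest-path lengths over
    all connected ordered pairs; pairs in different components are
    excluded and counted in ``n_disconnected_pairs``.
    """
    g = net.to_networkx() if isinstance(net, CooccurrenceNetwork) else net
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("network_stats needs at least 1 node")
    e = g.number_of_edges()
    mean_degree = 2 * e / n
    clustering = nx.average_clustering(g, count_zeros=count_low_degree_as_zero)
    path_sum = 0
    connected_pairs = 0
    for component in nx.connected_components(g):
        sub = g.subgraph(component)
        m = len(component)
        if m < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            path_sum += sum(dists.values())
        connected_pairs += m * (m - 1)
    total_pairs = n * (n - 1)
    cpl = path_sum / connected_pairs if connected_pairs else float("nan")
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        mean_degree=mean_degree,
        clustering_coefficient=float(clustering),
        characteristic_path_length=float(cpl),
        n_disconnected_pairs=total_pairs - connected_pairs,
    )


def export_graphml(net: CooccurrenceNetwork, path: str | Path) -> None:
    """Write the network as GraphML.

    Defined coordinates are written as float attributes; an undefined
    coordinate is simply absent from the node (an explicit, lossless
    sentinel — never serialized as 0).
    """
    nx.write_graphml(net.to_networkx(), str(path))


def import_graphml(path: str | Path) -> CooccurrenceNetwork:
    return CooccurrenceNetwork.from_networkx(nx.read_graphml(str(path)))


def edge_table(net: CooccurrenceNetwork) -> pd.DataFrame:
    return pd.DataFrame(net.edges, columns=["otu_a", "otu_b", "dissimilarity"])


def node_table(net: CooccurrenceNetwork) -> pd.DataFrame:
    degree: dict[str, int] = {otu: 0 for otu in net.nodes}
    for a, b, _ in net.edges:
        degree[a] += 1
        degree[b] += 1
    rows = [
        {
            "otu_id": otu,
            "phylum": phylum,
            "x": pos.x if pos.x is not None else np.nan,
            "y": pos.y if pos.y is not None else np.nan,
            "degree": degree[otu],
        }
        for otu, (phylum, pos) in net.nodes.items()
    ]
    return pd.DataFrame(rows, columns=["otu_id", "phylum", "x", "y", "degree"])
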