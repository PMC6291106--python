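"""Community detection, consensus overlap, and core-DSN extraction.

Four classic algorithms are run on the weighted disease similarity network:
fast greedy (Clauset-Newman-Moore modularity agglomeration), edge
betweenness (Girvan-Newman), walktrap (Pons-Latapy, 4-step random walks)
and spin glass (Reichardt-Bornholdt Potts model, simulated annealing,
gamma = 1). Their partitions are overlapped: two diseases belong to a
consensus community only if every algorithm (or a configurable quorum)
co-assigns them, and the consensus communities are the connected components
of that co-assignment graph. The core DSN is then the bottleneck diseases
plus every non-bottleneck member of a consensus community containing at
least one bottleneck.

Fast greedy, walktrap and spin glass are delegated to python-igraph; their
dendrograms are cut at the partition maximizing *weighted* modularity. The
Girvan-Newman loop is run explicitly (removing the edge of maximal weighted
betweenness, with similarity weights acting as traversal costs so that weak
ties attract shortest paths) because igraph's dendrogram cut ignores edge
weights when choosing the number of communities.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import igraph as ig
import networkx as nx
import pandas as pd

from .errors import ConfigError, IntegrityError

ALGORITHMS = ("fast_greedy", "edge_betweenness", "walktrap", "spin_glass")

_SPINGLASS_RESTARTS = 5


@dataclass
class Partition:
    """One algorithm's community assignment over the whole graph."""

    membership: dict[str, int]
    algorithm: str
    modularity: float

    def communities(self) -> list[set[str]]:
        by_label: dict[int, set[str]] = {}
        for node, lab in self.membership.items():
            by_label.setdefault(lab, set()).add(node)
        return [by_label[k] for k in sorted(by_label)]


@dataclass
class ConsensusCommunities:
    communities: list[set[str]]
    provenance: list[str] = field(default_factory=list)
    quorum: int = 0


@dataclass
class CoreDSN:
    bottlenecks: set[str]
    partners: set[str]
    subgraph: nx.Graph
    mean_edge_weight: float


def _to_igraph(graph: nx.Graph, nodes: Sequence[str]) -> ig.Graph:
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    g.es["weight"] = [graph.edges[a, b].get("weight", 1.0) for a, b in graph.edges]
    return g


def _cut_at_max_modularity(g: ig.Graph, dendrogram) -> list[int]:
    """Cut an igraph dendrogram at the weighted-modularity optimum."""
    best_q, best = -2.0, None
    max_k = g.vcount()
    for k in range(1, max_k + 1):
        try:
            membership = dendrogram.as_clustering(k).membership
        except (ig.InternalError, ValueError):  # not every cut level exists
            continue
        q = g.modularity(membership, weights="weight") if g.ecount() else 0.0
        if q > best_q + 1e-12:
            best_q, best = q, membership
    return best if best is not None else [0] * g.vcount()


def _girvan_newman(graph: nx.Graph) -> dict[str, int]:
    """Girvan-Newman with weighted edge betweenness, cut at max modularity.

    Similarity weights are used directly as traversal costs, so low-weight
    (weakly similar) edges concentrate shortest paths and are removed first.
    """
    work = graph.copy()
    best_q, best_comms = -2.0, [set(c) for c in nx.connected_components(work)]
    if graph.number_of_edges():
        q = nx.community.modularity(graph, best_comms, weight="weight")
        best_q = q
    while work.number_of_edges():
        eb = nx.edge_betweenness_centrality(work, weight="weight")
        edge = max(eb, key=lambda e: (eb[e], tuple(sorted(e))))
        work.remove_edge(*edge)
        comms = [set(c) for c in nx.connected_components(work)]
        q = nx.community.modularity(graph, comms, weight="weight")
        if q > best_q + 1e-12:
            best_q, best_comms = q, comms
    membership: dict[str, int] = {}
    for lab, comm in enumerate(sorted(best_comms, key=lambda c: sorted(c)[0])):
        for node in comm:
            membership[node] = lab
    return membership


def _detect_component(
    graph: nx.Graph, nodes: list[str], algorithm: str, seed: int | None
) -> dict[str, int]:
    if len(nodes) == 1 or graph.subgraph(nodes).number_of_edges() == 0:
        return {n: i for i, n in enumerate(sorted(nodes))}
    sub = graph.subgraph(nodes)
    if algorithm == "edge_betweenness":
        return _girvan_newman(sub)
    g = _to_igraph(sub, nodes)
    if algorithm == "fast_greedy":
        membership = _cut_at_max_modularity(
            g, g.community_fastgreedy(weights="weight")
        )
    elif algorithm == "walktrap":
        membership = _cut_at_max_modularity(
            g, g.community_walktrap(weights="weight", steps=4)
        )
    elif algorithm == "spin_glass":
        best_q, membership = -2.0, None
        for restart in range(_SPINGLASS_RESTARTS):
            ig.set_random_number_generator(
                random.Random((int(seed) * 1000 + restart) & 0x7FFFFFFF)
            )
            m = g.community_spinglass(
                weights="weight", gamma=1.0, spins=min(25, g.vcount()), cool_fact=0.99
            ).membership
            q = g.modularity(m, weights="weight")
            if q > best_q:
                best_q, membership = q, m
    else:
        raise ConfigError(f"unknown algorithm {algorithm!r}")
    return {n: membership[i] for i, n in enumerate(nodes)}


def detect(
    graph: nx.Graph, algorithm: str, seed: int | None = None
) -> Partition:
    """Run one community-detection algorithm on a weighted graph.

    Disconnected graphs are handled per component with disjoint labels.
    ``seed`` is required for the stochastic spin-glass annealer.
    """
    if algorithm not in ALGORITHMS:
        raise ConfigError(
            f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}"
        )
    if algorithm == "spin_glass" and seed is None:
        raise ConfigError("spin_glass requires a seed")
    membership: dict[str, int] = {}
    offset = 0
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for comp in components:
        local = _detect_component(graph, sorted(comp), algorithm, seed)
        for node, lab in local.items():
            membership[node] = lab + offset
        offset += max(local.values()) + 1
    if graph.number_of_edges():
        comms: dict[int, set[str]] = {}
        for n, lab in membership.items():
            comms.setdefault(lab, set()).add(n)
        q = nx.community.modularity(graph, list(comms.values()), weight="weight")
    else:
        q = 0.0
    return Partition(membership=membership, algorithm=algorithm, modularity=float(q))


def detect_all(
    graph: nx.Graph, seed: int, algorithms: Sequence[str] = ALGORITHMS
) -> list[Partition]:
    return [detect(graph, alg, seed=seed) for alg in algorithms]


def consensus(
    partitions: Sequence[Partition], quorum: int | None = None
) -> ConsensusCommunities:
    """Overlap partitions into consensus communities.

    A pair of nodes is consensus-linked when at least ``quorum`` partitions
    (default: all of them) place it in one community; consensus communities
    are the connected components, of size >= 2, of the resulting graph.
    """
    if len(partitions) < 2:
        raise ConfigError("consensus needs at least two partitions")
    node_sets = [frozenset(p.membership) for p in partitions]
    if len(set(node_sets)) != 1:
        raise IntegrityError("partitions cover different node sets")
    quorum = len(partitions) if quorum is None else quorum
    if not 1 <= quorum <= len(partitions):
        raise ConfigError("quorum out of range")
    nodes = sorted(node_sets[0])
    co = nx.Graph()
    co.add_nodes_from(nodes)
    for u, v in itertools.combinations(nodes, 2):
        agree = sum(p.membership[u] == p.membership[v] for p in partitions)
        if agree >= quorum:
            co.add_edge(u, v)
    comms = [set(c) for c in nx.connected_components(co) if len(c) >= 2]
    comms.sort(key=lambda c: sorted(c)[0])
    return ConsensusCommunities(
        communities=comms,
        provenance=[p.algorithm for p in partitions],
        quorum=quorum,
    )


def extract_core(
    consensus_result: ConsensusCommunities,
    bottlenecks: set[str],
    graph: nx.Graph,
) -> CoreDSN:
    """Bottlenecks plus their consensus-community partners, as a subgraph."""
    missing = bottlenecks - set(graph.nodes)
    if missing:
        raise IntegrityError(f"bottlenecks absent from graph: {sorted(missing)}")
    partners: set[str] = set()
    for comm in consensus_result.communities:
        if comm & bottlenecks:
            partners |= comm - bottlenecks
    core_nodes = bottlenecks | partners
    sub = graph.subgraph(core_nodes).copy()
    weights = [d["weight"] for _, _, d in sub.edges(data=True)]
    mean_w = float(sum(weights) / len(weights)) if weights else float("nan")
    return CoreDSN(
        bottlenecks=set(bottlenecks),
        partners=partners,
        subgraph=sub,
        mean_edge_weight=mean_w,
    )


def write_partitions(
    partitions: Sequence[Partition], path: str | Path
) -> None:
    """CSV writer: one row per (disease, algorithm) with its community."""
    rows = []
    for p in partitions:
        for node in sorted(p.membership):
            rows.append(
                {
                    "disease_id": node,
                    "algorithm": p.algorithm,
                    "community": p.membership[node],
                }
            )
    pd.DataFrame(rows, columns=["disease_id", "algorithm", "community"]).to_csv(
        path, index=False
    )


def write_core(core: CoreDSN, out_dir: str | Path) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "core_dsn.csv"
    rows = [
        {"disease_id": d, "role": "bottleneck" if d in core.bottlenecks else "partner"}
        for d in sorted(core.subgraph.nodes)
    ]
    pd.DataFrame(rows, columns=["disease_id", "role"]).to_csv(csv_path, index=False)
    gml = out / "core_dsn.graphml"
    nx.write_graphml(core.subgraph, gml)
    return {"csv": str(csv_path), "graphml": str(gml)}
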