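"""Ontology semantic similarity and the disease similarity network (DSN).

Pairwise similarity between disease terms follows Wang's graph-based
measure: each term's ancestors receive a semantic contribution (S-value)
that decays multiplicatively along ``is_a``/``part_of`` edges, and the
similarity of two terms is the summed contribution of their shared
ancestors relative to their total semantic values,

    S_A(A) = 1
    S_A(t) = max{ w_e * S_A(t') : t' is a child of t on a path to A }
    SV(A)  = sum_t S_A(t)
    sim(A, B) = sum_{t in T_A ∩ T_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B))

so sim is symmetric, lies in (0, 1] for terms sharing the root, and equals 1
exactly for identical ancestor structure.

The DSN has one node per scored disease and edge weights equal to the
similarity of their annotated terms. Two thresholding modes are supported:
``complete`` keeps every defined pair, while ``topk`` keeps, for each
disease, its k strongest partners, symmetrized by union (an edge survives
if either endpoint picked it — the "even after transposition" rule).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, IntegrityError

#: semantic contribution per edge relation
DEFAULT_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}


def read_obo_edges(path: str | Path) -> nx.DiGraph:
    """Read an OBO-style edge list CSV (``child_id,parent_id,relation``)."""
    frame = pd.read_csv(path, dtype=str)
    needed = {"child_id", "parent_id"}
    if not needed <= set(frame.columns):
        raise IntegrityError("ontology edge list needs child_id and parent_id columns")
    if "relation" not in frame.columns:
        frame["relation"] = "is_a"
    dag = nx.DiGraph()
    for child, parent, rel in frame[["child_id", "parent_id", "relation"]].itertuples(
        index=False
    ):
        dag.add_edge(child, parent, relation=rel)
    validate_dag(dag)
    return dag


def validate_dag(dag: nx.DiGraph) -> None:
    if dag.number_of_nodes() == 0:
        raise EmptyInputError("empty ontology")
    if not nx.is_directed_acyclic_graph(dag):
        raise IntegrityError("ontology contains a cycle")
    roots = [n for n in dag.nodes if dag.out_degree(n) == 0]
    if len(roots) != 1:
        raise IntegrityError(f"ontology must have exactly one root, found {roots}")


def _edge_weight(dag: nx.DiGraph, child: str, parent: str, weights) -> float:
    rel = dag.edges[child, parent].get("relation", "is_a")
    try:
        return weights[rel]
    except KeyError:
        raise ConfigError(f"no semantic weight for relation {rel!r}") from None


def _svalues(
    term: str, dag: nx.DiGraph, weights: Mapping[str, float]
) -> dict[str, float]:
    """Semantic contribution of each ancestor of ``term`` (term included)."""
    s = {term: 1.0}
    stack = [term]
    while stack:
        child = stack.pop()
        for parent in dag.successors(child):
            cand = _edge_weight(dag, child, parent, weights) * s[child]
            if cand > s.get(parent, 0.0):
                s[parent] = cand
                stack.append(parent)
    return s


def _ssum(values: Mapping[str, float]) -> float:
    return sum(values[k] for k in sorted(values))


def wang_similarity(
    a: str,
    b: str,
    dag: nx.DiGraph,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Wang semantic similarity of two ontology terms, in (0, 1]."""
    weights = DEFAULT_WEIGHTS if weights is None else weights
    for t in (a, b):
        if t not in dag:
            raise KeyError(f"term {t!r} not in ontology")
    sa = _svalues(a, dag, weights)
    sb = _svalues(b, dag, weights)
    # sorted iteration keeps float summation order (hence output bytes) stable
    shared = sorted(sa.keys() & sb.keys())
    num = sum(sa[t] + sb[t] for t in shared)
    return num / (_ssum(sa) + _ssum(sb))


def pairwise_similarity(
    diseases: Sequence[str],
    annotation: Mapping[str, str | None],
    dag: nx.DiGraph,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Symmetric similarity matrix over diseases; NaN where unannotated."""
    weights = DEFAULT_WEIGHTS if weights is None else weights
    diseases = list(diseases)
    terms = {d: annotation.get(d) for d in diseases}
    cache: dict[str, dict[str, float]] = {}
    for d, t in terms.items():
        if t is not None and t not in cache:
            if t not in dag:
                raise KeyError(f"annotation term {t!r} for {d!r} not in ontology")
            cache[t] = _svalues(t, dag, weights)
    n = len(diseases)
    mat = np.full((n, n), np.nan)
    sv = {t: _ssum(s) for t, s in cache.items()}
    for i, a in enumerate(diseases):
        ta = terms[a]
        if ta is None:
            continue
        mat[i, i] = 1.0
        for j in range(i + 1, n):
            tb = terms[diseases[j]]
            if tb is None:
                continue
            sa, sb = cache[ta], cache[tb]
            shared = sorted(sa.keys() & sb.keys())
            num = sum(sa[t] + sb[t] for t in shared)
            mat[i, j] = mat[j, i] = num / (sv[ta] + sv[tb])
    return pd.DataFrame(mat, index=diseases, columns=diseases)


def restrict_to_scored(matrix: pd.DataFrame) -> list[str]:
    """Diseases with at least one defined off-diagonal similarity."""
    scored = []
    for d in matrix.index:
        row = matrix.loc[d].drop(labels=[d])
        if row.notna().any():
            scored.append(d)
    return scored


def top_k_edges(matrix: pd.DataFrame, k: int = 3) -> list[tuple[str, str, float]]:
    """Union-symmetrized per-node top-k edge selection.

    For each disease the k highest-scoring partners are picked (ties broken
    by score descending then partner id ascending); an undirected edge is
    kept if either endpoint picked it.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    kept: set[tuple[str, str]] = set()
    for d in matrix.index:
        row = matrix.loc[d].drop(labels=[d]).dropna()
        partners = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        for partner, _score in partners:
            kept.add(tuple(sorted((d, partner))))
    return [(a, b, float(matrix.loc[a, b])) for a, b in sorted(kept)]


def build_dsn(
    matrix: pd.DataFrame,
    mode: str = "complete",
    k: int = 3,
    frequency: Mapping[str, int] | None = None,
    bottlenecks: set[str] | None = None,
) -> tuple[nx.Graph, dict[str, float]]:
    """Build the weighted DSN over scored diseases and report its stats.

    Returns the graph plus ``{"n_nodes", "n_edges", "avg_weight"}`` where
    ``avg_weight`` is the mean edge weight of the network.
    """
    if mode not in ("complete", "topk"):
        raise ConfigError(f"unknown DSN mode {mode!r}")
    scored = restrict_to_scored(matrix)
    if not scored:
        raise EmptyInputError("no scored diseases: cannot build a DSN")
    sub = matrix.loc[scored, scored]
    graph = nx.Graph()
    for d in scored:
        graph.add_node(
            d,
            frequency=int(frequency.get(d, 0)) if frequency else 0,
            bottleneck=bool(bottlenecks and d in bottlenecks),
        )
    if mode == "complete":
        for i, a in enumerate(scored):
            for b in scored[i + 1 :]:
                w = sub.loc[a, b]
                if pd.notna(w):
                    graph.add_edge(a, b, weight=float(w))
    else:
        for a, b, w in top_k_edges(sub, k=k):
            graph.add_edge(a, b, weight=w)
    weights = [d["weight"] for _, _, d in graph.edges(data=True)]
    stats = {
        "n_nodes": float(graph.number_of_nodes()),
        "n_edges": float(graph.number_of_edges()),
        "avg_weight": float(np.mean(weights)) if weights else float("nan"),
    }
    return graph, stats


def write_dsn(graph: nx.Graph, out_dir: str | Path) -> dict[str, str]:
    """GraphML and weighted edge-list CSV writers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gml = out / "dsn.graphml"
    nx.write_graphml(graph, gml)
    rows = sorted(
        (min(a, b), max(a, b), d["weight"]) for a, b, d in graph.edges(data=True)
    )
    csv_path = out / "dsn_edges.csv"
    pd.DataFrame(rows, columns=["disease_a", "disease_b", "score"]).to_csv(
        csv_path, index=False
    )
    return {"graphml": str(gml), "edges": str(csv_path)}


def write_similarity_long(matrix: pd.DataFrame, path: str | Path) -> None:
    """Long-format CSV (``disease_a,disease_b,score``) of a similarity matrix."""
    rows = []
    diseases = list(matrix.index)
    for i, a in enumerate(diseases):
        for b in diseases[i + 1 :]:
            v = matrix.loc[a, b]
            if pd.notna(v):
                rows.append({"disease_a": a, "disease_b": b, "score": float(v)})
    pd.DataFrame(rows, columns=["disease_a", "disease_b", "score"]).to_csv(
        path, index=False
    )
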