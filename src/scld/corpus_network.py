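"""Chemical-disease bipartite network and bottleneck-disease selection.

Diseases mined from the literature enter the pipeline with a term frequency
(how often the disease name occurs in the abstract corpus). Curated
chemical-disease associations link a subset of them to drugs; diseases with
no drug link are dropped, and the remaining high-frequency outliers — counts
strictly above both the 90th percentile of the drug-linked diseases and an
absolute cutoff of 10 — are flagged as "bottleneck" diseases.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, IntegrityError

FREQ_COLUMNS = ["disease_id", "name", "count"]
ASSOC_COLUMNS = ["chemical_id", "disease_id", "evidence"]


def read_term_frequency(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"disease_id": str, "name": str})
    missing = set(FREQ_COLUMNS) - set(frame.columns)
    if missing:
        raise IntegrityError(f"term-frequency table missing columns {sorted(missing)}")
    if frame["disease_id"].duplicated().any():
        dupes = frame.loc[frame["disease_id"].duplicated(), "disease_id"].tolist()
        raise IntegrityError(f"duplicate disease_id rows: {dupes}")
    if (frame["count"] < 0).any():
        raise IntegrityError("negative term-frequency counts")
    return frame[FREQ_COLUMNS]


def read_associations(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str)
    missing = {"chemical_id", "disease_id"} - set(frame.columns)
    if missing:
        raise IntegrityError(f"association table missing columns {sorted(missing)}")
    if "evidence" not in frame.columns:
        frame["evidence"] = "curated"
    return frame[ASSOC_COLUMNS]


def build_bipartite(assoc: pd.DataFrame, freq: pd.DataFrame) -> nx.Graph:
    """Bipartite chemical-disease graph from the association table.

    Duplicate (chemical, disease) pairs collapse to one edge; diseases with
    no chemical link are excluded entirely. Disease nodes carry their term
    frequency (``frequency``) and display name (``name``).
    """
    if assoc.empty or freq.empty:
        raise EmptyInputError("association and frequency tables must be non-empty")
    known = set(freq["disease_id"])
    offenders = sorted(set(assoc["disease_id"]) - known)
    if offenders:
        raise IntegrityError(
            f"association rows reference unknown disease_ids: {offenders}"
        )
    counts = dict(zip(freq["disease_id"], freq["count"]))
    names = dict(zip(freq["disease_id"], freq["name"]))
    graph = nx.Graph()
    pairs = assoc[["chemical_id", "disease_id"]].drop_duplicates()
    for chem, dis in pairs.itertuples(index=False):
        graph.add_node(chem, bipartite="chemical")
        graph.add_node(
            dis, bipartite="disease", frequency=int(counts[dis]), name=names[dis]
        )
        graph.add_edge(chem, dis)
    return graph


def disease_nodes(network: nx.Graph) -> list[str]:
    return sorted(
        n for n, d in network.nodes(data=True) if d.get("bipartite") == "disease"
    )


def select_bottlenecks(
    freq: pd.DataFrame,
    network: nx.Graph,
    percentile: float = 90.0,
    min_count: int = 10,
) -> set[str]:
    """Diseases whose count strictly exceeds both outlier cutoffs.

    The percentile is computed over the drug-linked (network) diseases only,
    by linear interpolation between order statistics; both criteria are
    strict and conjunctive.
    """
    if not 0 < percentile < 100:
        raise ConfigError("percentile must lie in (0, 100)")
    linked = disease_nodes(network)
    if not linked:
        raise EmptyInputError("bipartite network contains no disease nodes")
    counts = dict(zip(freq["disease_id"], freq["count"]))
    values = np.array([counts[d] for d in linked], dtype=float)
    cutoff = np.percentile(values, percentile)  # linear interpolation
    return {
        d for d in linked if counts[d] > cutoff and counts[d] > min_count
    }


def write_bipartite(network: nx.Graph, out_dir: str | Path) -> dict[str, str]:
    """GraphML plus edge-list CSV serialization."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gml = out / "bipartite.graphml"
    nx.write_graphml(network, gml)
    rows = sorted(
        (a, b) if network.nodes[a].get("bipartite") == "chemical" else (b, a)
        for a, b in network.edges
    )
    csv_path = out / "bipartite_edges.csv"
    pd.DataFrame(rows, columns=["chemical_id", "disease_id"]).to_csv(
        csv_path, index=False
    )
    return {"graphml": str(gml), "edges": str(csv_path)}
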