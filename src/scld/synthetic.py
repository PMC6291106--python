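"""Synthetic inputs with known ground truth for the whole pipeline.

Three families of inputs are emulated:

* a literature-mining surrogate: Zipf-distributed disease term frequencies
  with a handful of planted high-frequency "bottleneck" diseases, plus a
  curated chemical-disease association table;
* a rooted ontology DAG of disease terms with planted comorbid groups
  (each group annotated to sibling leaves under a common parent, so that
  within-group semantic similarity is high);
* monthly 0-100 integer relative-search-volume panels built from a linear
  trend, 6- and 12-month harmonics with a phase shared inside each planted
  comorbid group, and additive Gaussian noise, max-rescaled to 100 the way
  Google Trends normalizes its exports.

Every generator is a pure function of its seed: the same configuration
reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import trends_io
from .errors import ConfigError
from .trends_io import MONTHLY, RSVSeries

SEVERE = "severe"
MODERATE = "moderate"
MILD = "mild"
LABELS = (SEVERE, MODERATE, MILD)

#: The twelve core comorbid lifestyle diseases used as default ground truth,
#: stratified by the seasonality class the generator should emulate.
CORE_DISEASE_LABELS: dict[str, str] = {
    "asthma": SEVERE,
    "obesity": SEVERE,
    "hypertension": SEVERE,
    "fibrosis": SEVERE,
    "fatigue": MODERATE,
    "edema": MODERATE,
    "apnea": MODERATE,
    "acidosis": MILD,
    "hyperglycemia": MILD,
    "esophagitis": MILD,
    "hypercholesterolemia": MILD,
    "hyperhomocysteinemia": MILD,
}

#: High literature-frequency diseases planted as bottlenecks in the corpus.
DEFAULT_BOTTLENECKS = ("edema", "hypertension", "asthma", "fatigue", "apnea", "obesity")


@dataclass(frozen=True)
class DiseaseClassParams:
    """Signal-shape parameters for one seasonality class.

    base_level     mean raw level before max-100 rescaling (RSV-like units)
    trend_slope    linear drift per month (negative = declining interest)
    amp6, amp12    amplitudes of the semi-annual and annual harmonics
    phase          radians; shared by every disease of the class, so the
                   class forms one comorbid group with aligned seasonality
    spike          one-off surge added at a random month; models the spiky
                   low-volume terms whose mean RSV sits far below the peak
    """

    base_level: float
    trend_slope: float
    amp6: float
    amp12: float
    phase: float = 0.0
    spike: float = 0.0


DEFAULT_CLASS_PARAMS: dict[str, DiseaseClassParams] = {
    # strong semi-annual rhythm plus the pronounced declining trend that
    # high-volume chronic-disease searches showed over 2004-2016
    SEVERE: DiseaseClassParams(
        base_level=60.0, trend_slope=-0.15, amp6=8.0, amp12=4.0, phase=0.0
    ),
    # appreciable volume but weak seasonality and a mild upward drift
    MODERATE: DiseaseClassParams(
        base_level=45.0, trend_slope=0.05, amp6=1.0, amp12=1.0, phase=np.pi
    ),
    # low-volume terms: tiny base with a single spike, so the max-100
    # rescaling leaves the mean RSV well under the reporting threshold
    MILD: DiseaseClassParams(
        base_level=4.0, trend_slope=0.0, amp6=0.5, amp12=0.5, phase=0.0, spike=40.0
    ),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic study, with defaults matching the study
    conditions the pipeline is meant to operate under (156 monthly samples,
    Jan 2004 - Dec 2016; 73 candidate diseases with 6 bottlenecks)."""

    seed: int = 0
    n_diseases: int = 73
    n_chemicals: int = 6
    ontology_branching: int = 3
    freq_zipf_exponent: float = 1.8
    n_months: int = 156
    start: str = "2004-01"
    noise_sd: float = 3.0
    planted_labels: Mapping[str, str] = field(
        default_factory=lambda: dict(CORE_DISEASE_LABELS)
    )
    planted_bottlenecks: Sequence[str] = DEFAULT_BOTTLENECKS
    class_params: Mapping[str, DiseaseClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    annotation_rate: float = 0.6
    assoc_dropout: float = 0.1

    def __post_init__(self):
        if self.n_months < 24:
            raise ConfigError("n_months must be >= 24 (two full annual cycles)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_diseases < len(self.planted_labels):
            raise ConfigError("n_diseases smaller than the planted label set")
        if self.n_chemicals < 1:
            raise ConfigError("need at least one chemical")
        if not 0 <= self.annotation_rate <= 1:
            raise ConfigError("annotation_rate must be in [0, 1]")
        for disease, label in self.planted_labels.items():
            if label not in LABELS:
                raise ConfigError(f"unknown class {label!r} for {disease!r}")
        for label, p in self.class_params.items():
            if p.amp6 < 0 or p.amp12 < 0 or p.spike < 0:
                raise ConfigError(f"negative amplitude in class {label!r}")
        for b in self.planted_bottlenecks:
            if b not in self.planted_labels:
                raise ConfigError(f"bottleneck {b!r} not among planted diseases")


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, stream])


# ---------------------------------------------------------------------------
# ontology


def gen_ontology(seed: int, n_terms: int, branching: int = 3) -> nx.DiGraph:
    """Random rooted ontology DAG with child->parent ``is_a`` edges.

    Every non-root term has one parent (two with small probability, as real
    disease ontologies are multi-parent DAGs, not trees) and no node exceeds
    ``branching`` children from the primary attachment process.
    """
    if n_terms < 2:
        raise ConfigError("an ontology needs at least a root and one term")
    if branching < 1:
        raise ConfigError("branching must be >= 1")
    rng = _rng(seed, 101)
    dag = nx.DiGraph()
    names = [f"T{i:04d}" for i in range(n_terms)]
    dag.add_node(names[0], name="root")
    children_count = {names[0]: 0}
    for i in range(1, n_terms):
        open_slots = [t for t in names[:i] if children_count[t] < branching]
        if not open_slots:  # every node saturated: attach anywhere
            open_slots = names[:i]
        parent = open_slots[rng.integers(len(open_slots))]
        dag.add_edge(names[i], parent, relation="is_a")
        children_count[parent] = children_count.get(parent, 0) + 1
        children_count[names[i]] = 0
        # occasional second parent keeps the graph a genuine DAG
        if i >= 2 and rng.random() < 0.15:
            others = [t for t in names[:i] if t != parent]
            second = others[rng.integers(len(others))]
            dag.add_edge(names[i], second, relation="is_a")
    return dag


def gen_annotation(
    config: SyntheticConfig, dag: nx.DiGraph, diseases: Sequence[str]
) -> tuple[nx.DiGraph, dict[str, str | None]]:
    """Map each disease to at most one ontology term.

    Planted (core) diseases are always annotated; each class is given fresh
    sibling leaf terms under a common randomly chosen parent, which plants
    recoverable community structure in the similarity network. Remaining
    diseases are annotated to random existing terms with probability
    ``annotation_rate`` and left unannotated otherwise.
    """
    rng = _rng(config.seed, 202)
    dag = dag.copy()
    annotation: dict[str, str | None] = {}
    internal = sorted(n for n in dag.nodes if dag.in_degree(n) > 0 or n == "T0000")
    by_label: dict[str, list[str]] = {}
    for d in diseases:
        lab = config.planted_labels.get(d)
        if lab is not None:
            by_label.setdefault(lab, []).append(d)
    hosts = rng.choice(len(internal), size=len(by_label), replace=False)
    counter = dag.number_of_nodes()
    for (label, members), host_i in zip(sorted(by_label.items()), hosts):
        host = internal[int(host_i)]
        for d in sorted(members):
            leaf = f"T{counter:04d}"
            counter += 1
            dag.add_edge(leaf, host, relation="is_a")
            annotation[d] = leaf
    terms = sorted(dag.nodes)
    for d in diseases:
        if d in annotation:
            continue
        if rng.random() < config.annotation_rate:
            annotation[d] = terms[int(rng.integers(len(terms)))]
        else:
            annotation[d] = None
    return dag, annotation


# ---------------------------------------------------------------------------
# corpus tables


def disease_names(config: SyntheticConfig) -> list[str]:
    """Planted disease names first, anonymous fillers after."""
    planted = sorted(config.planted_labels)
    fillers = [
        f"ha_disorder_{i:03d}" for i in range(config.n_diseases - len(planted))
    ]
    return planted + fillers


def gen_corpus(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Term-frequency and chemical-disease association tables.

    Non-bottleneck counts follow a truncated Zipf law capped at the absolute
    bottleneck cutoff (10), so the planted bottlenecks are exactly the
    diseases exceeding both the 90th-percentile and the count-10 rules.
    Every planted disease keeps at least one chemical link; fillers drop out
    of the bipartite network with probability ``assoc_dropout``.
    """
    rng = _rng(config.seed, 303)
    names = disease_names(config)
    bottlenecks = set(config.planted_bottlenecks)
    counts = {}
    raw = rng.zipf(config.freq_zipf_exponent, size=len(names))
    for name, z in zip(names, raw):
        counts[name] = int(min(z, 10))
    # bottleneck counts: strictly above both cutoffs, spread out for realism
    for rank, name in enumerate(sorted(bottlenecks)):
        counts[name] = int(20 + 15 * rank + rng.integers(0, 5))
    freq = pd.DataFrame(
        {
            "disease_id": [f"D{i:03d}" for i in range(len(names))],
            "name": names,
            "count": [counts[n] for n in names],
        }
    )

    chems = [f"C{i:02d}" for i in range(config.n_chemicals)]
    rows = []
    planted = set(config.planted_labels)
    for name in names:
        if name not in planted and rng.random() < config.assoc_dropout:
            continue  # disease loses its drug links -> filtered downstream
        n_links = 1 + int(rng.integers(0, min(3, config.n_chemicals)))
        picked = rng.choice(len(chems), size=n_links, replace=False)
        for ci in sorted(int(c) for c in picked):
            rows.append(
                {
                    "chemical_id": chems[ci],
                    "disease_id": f"D{names.index(name):03d}",
                    "evidence": "curated",
                }
            )
    assoc = pd.DataFrame(rows, columns=["chemical_id", "disease_id", "evidence"])
    return freq, assoc


# ---------------------------------------------------------------------------
# RSV panels


def _raw_signal(
    t: np.ndarray, p: DiseaseClassParams, rng: np.random.Generator, noise_sd: float
) -> np.ndarray:
    s = (
        p.base_level
        + p.trend_slope * t
        + p.amp6 * np.cos(2 * np.pi * t / 6.0 + p.phase)
        + p.amp12 * np.cos(2 * np.pi * t / 12.0 + p.phase)
    )
    if noise_sd > 0:
        s = s + rng.normal(0.0, noise_sd, size=len(t))
    if p.spike > 0:
        s[int(rng.integers(len(t)))] += p.spike
    return s


def _to_rsv(s: np.ndarray) -> np.ndarray:
    """Google-Trends normalization: scale the max to 100, clip, round."""
    top = s.max()
    if top <= 0:
        return np.zeros_like(s, dtype=int)
    scaled = np.clip(s * (100.0 / top), 0.0, 100.0)
    return np.round(scaled).astype(int)


def gen_rsv_panel(
    config: SyntheticConfig, geo: str = "Worldwide", phase_offset: float = 0.0
) -> dict[str, RSVSeries]:
    """Monthly RSV series for every planted disease.

    ``phase_offset`` shifts every harmonic by the given angle; generating a
    second panel with ``phase_offset=pi`` yields the anti-phase counterpart
    of the first (a Southern-hemisphere analogue).
    """
    t = np.arange(config.n_months, dtype=float)
    index = pd.date_range(config.start, periods=config.n_months, freq="MS")
    panel: dict[str, RSVSeries] = {}
    for i, disease in enumerate(sorted(config.planted_labels)):
        label = config.planted_labels[disease]
        base = config.class_params[label]
        p = DiseaseClassParams(
            base_level=base.base_level,
            trend_slope=base.trend_slope,
            amp6=base.amp6,
            amp12=base.amp12,
            phase=base.phase + phase_offset,
            spike=base.spike,
        )
        rng = _rng(config.seed, 404 + i)
        values = _to_rsv(_raw_signal(t, p, rng, config.noise_sd))
        panel[disease] = RSVSeries(
            term=disease,
            geo=geo,
            granularity=MONTHLY,
            values=pd.Series(values.astype(float), index=index, name=disease),
        )
    return panel


def gen_panel(config: SyntheticConfig, **kwargs) -> trends_io.RSVPanel:
    """Aligned panel convenience wrapper around :func:`gen_rsv_panel`."""
    series = gen_rsv_panel(config, **kwargs)
    return trends_io.align_panel([series[k] for k in sorted(series)])


# ---------------------------------------------------------------------------
# one-call bundle


@dataclass
class SyntheticInputs:
    config: SyntheticConfig
    ontology: nx.DiGraph
    annotation: dict[str, str | None]
    term_frequency: pd.DataFrame
    associations: pd.DataFrame
    panel: trends_io.RSVPanel


def gen_all(config: SyntheticConfig) -> SyntheticInputs:
    """Generate every pipeline input from one seed."""
    n_terms = max(2, config.n_diseases // 2)
    dag = gen_ontology(config.seed, n_terms, config.ontology_branching)
    names = disease_names(config)
    dag, annotation = gen_annotation(config, dag, names)
    freq, assoc = gen_corpus(config)
    return SyntheticInputs(
        config=config,
        ontology=dag,
        annotation=annotation,
        term_frequency=freq,
        associations=assoc,
        panel=gen_panel(config),
    )


def write_inputs(inputs: SyntheticInputs, out_dir) -> dict[str, str]:
    """Serialize generated inputs in the same dialects the readers consume."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    freq_path = out / "term_frequency.csv"
    inputs.term_frequency.to_csv(freq_path, index=False)
    paths["term_frequency"] = str(freq_path)
    assoc_path = out / "associations.csv"
    inputs.associations.to_csv(assoc_path, index=False)
    paths["associations"] = str(assoc_path)
    onto_path = out / "ontology_edges.csv"
    edges = sorted(
        (c, p, d.get("relation", "is_a"))
        for c, p, d in inputs.ontology.edges(data=True)
    )
    pd.DataFrame(edges, columns=["child_id", "parent_id", "relation"]).to_csv(
        onto_path, index=False
    )
    paths["ontology"] = str(onto_path)
    ann_path = out / "annotation.csv"
    pd.DataFrame(
        [
            {"disease": d, "term": inputs.annotation[d] or ""}
            for d in sorted(inputs.annotation)
        ]
    ).to_csv(ann_path, index=False)
    paths["annotation"] = str(ann_path)
    panel_path = out / "rsv_panel.csv"
    trends_io.write_gt_csv(inputs.panel, panel_path)
    paths["panel"] = str(panel_path)
    return paths
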