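"""Shape-based clustering of RSV series and severe/moderate/mild labelling.

The shape-based distance (SBD) between two series is one minus the maximum
coefficient-normalized cross-correlation over all integer alignments of
their z-normalized versions:

    NCC_c(x, y; s) = sum_t x~_t * y~_{t+s} / (||x~|| * ||y~||)
    SBD(x, y)      = 1 - max_s NCC_c(x, y; s)        in [0, 2]

SBD is scale- and shift-invariant and tolerant of phase lags, which makes
it the natural dissimilarity for comparing seasonal search profiles. (It is
symmetric and zero on identical shapes but does not satisfy the triangle
inequality.)

The final classification of the core comorbid diseases:

1. diseases whose mean RSV falls below a threshold (default 20) are *mild*
   and excluded from further testing;
2. retained diseases are tested with the seasonal Mann-Kendall statistic,
   an FFT periodogram and the harmonic seasonality F-test;
3. retained diseases are cut into two shape groups (average-linkage
   clustering of the SBD matrix) and two trend groups (clustering of
   pairwise |delta z| of the seasonal Mann-Kendall scores);
4. *severe* diseases share both the benchmark disease's shape group and its
   trend group and have a significant seasonal Mann-Kendall trend; the
   remaining retained diseases are *moderate*.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as _linkage
from scipy.signal import correlate
from scipy.spatial.distance import squareform

from . import seasonality
from .errors import ConfigError, EmptyInputError
from .trends_io import RSVPanel

SEVERE = "severe"
MODERATE = "moderate"
MILD = "mild"


def znorm(x: Sequence[float]) -> np.ndarray:
    """Z-score normalization; a constant series maps to all zeros."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:  # constant up to representation, incl. fp-noise std
        return np.zeros_like(x)
    return (x - x.mean()) / x.std()


def sbd(x: Sequence[float], y: Sequence[float]) -> float:
    """Shape-based distance via FFT cross-correlation over all shifts."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ConfigError("series must have equal length")
    if len(x) < 2:
        raise ConfigError("series must have length >= 2")
    zx, zy = znorm(x), znorm(y)
    denom = np.linalg.norm(zx) * np.linalg.norm(zy)
    if denom == 0:
        return 0.0 if np.array_equal(zx, zy) else 1.0
    cc = correlate(zx, zy, mode="full", method="fft")
    dist = 1.0 - cc.max() / denom
    return float(min(max(dist, 0.0), 2.0))


def sbd_matrix(panel: RSVPanel | pd.DataFrame) -> pd.DataFrame:
    """Symmetric zero-diagonal SBD matrix over the panel's terms."""
    frame = panel.frame if isinstance(panel, RSVPanel) else panel
    terms = list(frame.columns)
    n = len(terms)
    mat = np.zeros((n, n))
    znormed = {t: znorm(frame[t].to_numpy()) for t in terms}
    norms = {t: np.linalg.norm(z) for t, z in znormed.items()}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = terms[i], terms[j]
            denom = norms[a] * norms[b]
            if denom == 0:
                d = 0.0 if np.array_equal(znormed[a], znormed[b]) else 1.0
            else:
                cc = correlate(znormed[a], znormed[b], mode="full", method="fft")
                d = float(min(max(1.0 - cc.max() / denom, 0.0), 2.0))
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=terms, columns=terms)


def hcluster_cut(
    dist: pd.DataFrame, linkage: str = "average", k: int = 2
) -> dict[str, int]:
    """Agglomerative clustering of a distance matrix cut into k groups.

    Items are processed in lexicographic order so that merge tie-breaking is
    deterministic. Returns item -> cluster label (1-based).
    """
    items = sorted(dist.index)
    n = len(items)
    if k > n:
        raise ConfigError(f"cannot cut {n} items into {k} clusters")
    if n == 1:
        return {items[0]: 1}
    square = dist.loc[items, items].to_numpy(dtype=float)
    square = (square + square.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(square, 0.0)
    Z = _linkage(squareform(square, checks=False), method=linkage)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return {item: int(lab) for item, lab in zip(items, labels)}


@dataclass
class SeasonalClassification:
    """Final labels and the per-disease evidence backing them."""

    labels: dict[str, str]
    evidence: pd.DataFrame
    benchmark_term: str

    def by_label(self, label: str) -> set[str]:
        return {d for d, lab in self.labels.items() if lab == label}


EVIDENCE_COLUMNS = [
    "term",
    "label",
    "mean_rsv",
    "smk_z",
    "smk_p",
    "seasonal",
    "dominant_period_1",
    "dominant_period_2",
    "shape_cluster",
    "trend_cluster",
]


def classify_scld(
    panel: RSVPanel,
    core_diseases: Sequence[str],
    benchmark_term: str,
    rsv_threshold: float = 20.0,
    alpha: float = 0.05,
    period: int = 12,
    linkage: str = "average",
) -> SeasonalClassification:
    """Classify the core comorbid diseases as severe / moderate / mild."""
    core = sorted(set(core_diseases) | {benchmark_term})
    missing = [d for d in core if d not in panel.terms]
    if missing:
        raise ConfigError(f"panel lacks core diseases: {missing}")
    means = {d: float(panel.series(d).mean()) for d in core}
    if means[benchmark_term] < rsv_threshold:
        raise ConfigError(
            f"benchmark {benchmark_term!r} has mean RSV {means[benchmark_term]:.2f} "
            f"below the retention threshold {rsv_threshold}"
        )
    mild = {d for d in core if means[d] < rsv_threshold}
    retained = [d for d in core if d not in mild]

    smk = {
        d: seasonality.seasonal_mann_kendall(
            panel.series(d), period=period, granularity=panel.granularity
        )
        for d in retained
    }
    seasonal_flag, dom = {}, {}
    for d in retained:
        vals = panel.series(d).to_numpy(dtype=float)
        _, _, flag = seasonality.seasonality_ftest(vals, period=period, alpha=alpha)
        seasonal_flag[d] = flag
        periods, power = seasonality.periodogram(vals)
        dom[d] = seasonality.dominant_periods(periods, power, m=2)

    if len(retained) >= 2:
        shape = hcluster_cut(
            sbd_matrix(panel.frame[retained]), linkage=linkage, k=min(2, len(retained))
        )
        zvals = {d: smk[d].z for d in retained}
        zmat = pd.DataFrame(
            [[abs(zvals[a] - zvals[b]) for b in retained] for a in retained],
            index=retained,
            columns=retained,
        )
        trend = hcluster_cut(zmat, linkage=linkage, k=min(2, len(retained)))
    else:
        shape = {d: 1 for d in retained}
        trend = {d: 1 for d in retained}

    labels: dict[str, str] = {d: MILD for d in mild}
    for d in retained:
        same_groups = (
            shape[d] == shape[benchmark_term] and trend[d] == trend[benchmark_term]
        )
        labels[d] = SEVERE if same_groups and smk[d].p < alpha else MODERATE

    rows = []
    for d in core:
        rows.append(
            {
                "term": d,
                "label": labels[d],
                "mean_rsv": means[d],
                "smk_z": smk[d].z if d in smk else np.nan,
                "smk_p": smk[d].p if d in smk else np.nan,
                "seasonal": seasonal_flag.get(d, False),
                "dominant_period_1": dom[d][0] if d in dom else np.nan,
                "dominant_period_2": dom[d][1] if d in dom else np.nan,
                "shape_cluster": shape.get(d, 0),
                "trend_cluster": trend.get(d, 0),
            }
        )
    evidence = pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)
    return SeasonalClassification(
        labels=labels, evidence=evidence, benchmark_term=benchmark_term
    )


def write_classification(
    result: SeasonalClassification, out_dir: str | Path
) -> dict[str, str]:
    """CSV evidence table plus a JSON label summary."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "classification.csv"
    result.evidence.to_csv(csv_path, index=False)
    json_path = out / "classification.json"
    payload = {
        "benchmark_term": result.benchmark_term,
        "labels": {d: result.labels[d] for d in sorted(result.labels)},
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return {"csv": str(csv_path), "json": str(json_path)}
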