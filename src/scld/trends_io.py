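"""Reading and writing Google-Trends-style relative search volume (RSV) data.

Google Trends exports ("multiTimeline.csv") carry a short preamble, a header
row such as ``Month,asthma: (Worldwide)`` and one row per period with integer
search volumes scaled to a 0-100 range; cells below one are printed ``<1``.
This module parses that dialect into :class:`RSVSeries` objects, aligns
several series into an :class:`RSVPanel` on a shared calendar, and serializes
pipeline outputs (trend-test tables, distance matrices) as deterministic CSV.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, GranularityError, ParseError

MONTHLY = "monthly"
WEEKLY = "weekly"

_HEADER_CELLS = {"Month": MONTHLY, "Week": WEEKLY}
_TERM_GEO = re.compile(r"^(?P<term>.*?):\s*\((?P<geo>[^)]*)\)\s*$")
_MAX_PREAMBLE = 3


def _check_regular(index: pd.DatetimeIndex, granularity: str) -> None:
    if len(index) < 2:
        return
    if granularity == MONTHLY:
        expected = pd.date_range(index[0], periods=len(index), freq="MS")
        ok = index.equals(expected)
    else:
        diffs = np.diff(index.values).astype("timedelta64[D]")
        ok = bool((diffs == np.timedelta64(7, "D")).all())
    if not ok:
        raise ParseError(f"irregular {granularity} time index")


@dataclass
class RSVSeries:
    """One search term's relative search volume over a regular calendar.

    ``values`` is a pandas Series indexed by the first day of each period.
    ``benchmark_term`` records the reference disease the query was combined
    with (Google performs that joint normalization server-side; it is
    metadata only and never rescaled here).
    """

    term: str
    geo: str
    granularity: str
    values: pd.Series
    benchmark_term: str | None = None

    def __post_init__(self):
        if self.granularity not in (MONTHLY, WEEKLY):
            raise GranularityError(f"unknown granularity {self.granularity!r}")
        idx = pd.DatetimeIndex(self.values.index)
        if not idx.is_monotonic_increasing:
            raise ParseError(f"non-monotone dates for term {self.term!r}")
        _check_regular(idx, self.granularity)
        vals = np.asarray(self.values, dtype=float)
        if len(vals) and (vals.min() < 0 or vals.max() > 100):
            raise ValueError(f"RSV values outside [0, 100] for {self.term!r}")
        self.values = pd.Series(vals, index=idx, name=self.term)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RSVPanel:
    """Several RSV series joined on a common time index."""

    frame: pd.DataFrame
    geo: str
    granularity: str
    benchmark_term: str | None = None

    @property
    def terms(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def index(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame.index)

    def series(self, term: str) -> pd.Series:
        return self.frame[term]

    def __len__(self) -> int:
        return len(self.frame)


def _parse_value(cell: str, sub1_policy: float, line: int) -> float:
    cell = cell.strip()
    if cell == "<1":
        return float(sub1_policy)
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"unparseable RSV cell {cell!r}", line=line) from None


def read_gt_csv(
    path: str | Path,
    sub1_policy: float = 0.5,
    benchmark_term: str | None = None,
) -> list[RSVSeries]:
    """Parse a Google-Trends CSV export into one series per data column.

    Tolerates up to three preamble lines (e.g. ``Category: All categories``
    plus a blank line) before the ``Month,...`` / ``Week,...`` header.
    ``<1`` cells are replaced by ``sub1_policy``.
    """
    text = Path(path).read_text(encoding="utf-8")
    return parse_gt_text(text, sub1_policy=sub1_policy, benchmark_term=benchmark_term)


def parse_gt_text(
    text: str,
    sub1_policy: float = 0.5,
    benchmark_term: str | None = None,
) -> list[RSVSeries]:
    rows = list(csv.reader(io.StringIO(text)))
    header_at = None
    for i, row in enumerate(rows):
        if row and row[0].strip() in _HEADER_CELLS:
            header_at = i
            break
        if i >= _MAX_PREAMBLE:
            break
    if header_at is None:
        raise ParseError("no Month/Week header found within the preamble window")
    header = [c.strip() for c in rows[header_at]]
    granularity = _HEADER_CELLS[header[0]]
    n_cols = len(header)
    if n_cols < 2:
        raise ParseError("header defines no data columns", line=header_at + 1)

    terms, geos = [], []
    for cell in header[1:]:
        m = _TERM_GEO.match(cell)
        if m:
            terms.append(m.group("term").strip())
            geos.append(m.group("geo").strip())
        else:
            terms.append(cell)
            geos.append("Unknown")

    dates: list[pd.Timestamp] = []
    columns: list[list[float]] = [[] for _ in terms]
    fmt = "%Y-%m" if granularity == MONTHLY else "%Y-%m-%d"
    for offset, row in enumerate(rows[header_at + 1 :]):
        line = header_at + 2 + offset
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != n_cols:
            raise ParseError(
                f"expected {n_cols} cells, found {len(row)}", line=line
            )
        try:
            ts = pd.Timestamp(pd.to_datetime(row[0].strip(), format=fmt))
        except ValueError:
            raise ParseError(f"bad date {row[0]!r}", line=line) from None
        if dates and ts <= dates[-1]:
            raise ParseError(f"non-monotone date {row[0]!r}", line=line)
        dates.append(ts)
        for j in range(len(terms)):
            columns[j].append(_parse_value(row[j + 1], sub1_policy, line))

    if not dates:
        raise ParseError("no data rows")
    index = pd.DatetimeIndex(dates)
    return [
        RSVSeries(
            term=terms[j],
            geo=geos[j],
            granularity=granularity,
            values=pd.Series(columns[j], index=index, name=terms[j]),
            benchmark_term=benchmark_term,
        )
        for j in range(len(terms))
    ]


def align_panel(series_list: Sequence[RSVSeries]) -> RSVPanel:
    """Join series on the intersection of their time ranges."""
    if not series_list:
        raise EmptyInputError("no series to align")
    grans = {s.granularity for s in series_list}
    if len(grans) > 1:
        raise GranularityError(f"mixed granularities: {sorted(grans)}")
    index = series_list[0].values.index
    for s in series_list[1:]:
        index = index.intersection(s.values.index)
    if len(index) == 0:
        raise EmptyInputError("series have no overlapping time range")
    frame = pd.DataFrame(
        {s.term: s.values.reindex(index) for s in series_list}, index=index
    )
    geos = {s.geo for s in series_list}
    benchmarks = {s.benchmark_term for s in series_list}
    return RSVPanel(
        frame=frame,
        geo=geos.pop() if len(geos) == 1 else "mixed",
        granularity=series_list[0].granularity,
        benchmark_term=benchmarks.pop() if len(benchmarks) == 1 else None,
    )


def write_gt_csv(panel: RSVPanel, path: str | Path) -> None:
    """Serialize a panel back into the Google-Trends export dialect."""
    path = Path(path)
    fmt = "%Y-%m" if panel.granularity == MONTHLY else "%Y-%m-%d"
    head = "Month" if panel.granularity == MONTHLY else "Week"
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("Category: All categories\n\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow([head] + [f"{t}: ({panel.geo})" for t in panel.terms])
        for ts, row in panel.frame.iterrows():
            cells = [ts.strftime(fmt)]
            for v in row:
                cells.append(f"{v:g}")
            writer.writerow(cells)


def panel_to_series(panel: RSVPanel) -> list[RSVSeries]:
    return [
        RSVSeries(
            term=t,
            geo=panel.geo,
            granularity=panel.granularity,
            values=panel.frame[t],
            benchmark_term=panel.benchmark_term,
        )
        for t in panel.terms
    ]


# ---------------------------------------------------------------------------
# result serialization

MK_COLUMNS = ["term", "n", "S", "varS", "z", "tau", "p"]


def write_mk_table(results: Mapping[str, object], path: str | Path) -> None:
    """Write Mann-Kendall results as CSV with a fixed schema.

    ``results`` maps term -> MKResult (any object with n, S, varS, z, tau, p).
    """
    rows = []
    for term in sorted(results):
        r = results[term]
        rows.append(
            {
                "term": term,
                "n": r.n,
                "S": r.S,
                "varS": r.varS,
                "z": r.z,
                "tau": r.tau,
                "p": r.p,
            }
        )
    pd.DataFrame(rows, columns=MK_COLUMNS).to_csv(path, index=False)


STATS_COLUMNS = [
    "term",
    "average_rsv",
    "mk_p",
    "mk_tau",
    "mk_z",
    "mk_S",
    "mk_varS",
    "smk_p",
    "smk_z",
    "smk_S",
    "smk_varS",
    "seasonal",
    "periodicity_months",
]


def write_stats_table(rows: Iterable[Mapping[str, object]], path: str | Path) -> None:
    """Write the per-disease trend/seasonality summary table."""
    frame = pd.DataFrame(list(rows), columns=STATS_COLUMNS)
    frame.to_csv(path, index=False)


def write_distance_long(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a symmetric distance/similarity matrix in long format."""
    items = sorted(matrix.index)
    rows = []
    for i, a in enumerate(items):
        for b in items[i + 1 :]:
            val = matrix.loc[a, b]
            if pd.isna(val):
                continue
            rows.append({"item_a": a, "item_b": b, "value": float(val)})
    pd.DataFrame(rows, columns=["item_a", "item_b", "value"]).to_csv(path, index=False)


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n",
        encoding="utf-8",
    )
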