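"""Trend and seasonality statistics for RSV time series.

Implements the battery of tests applied to each disease's search-volume
series:

* Mann-Kendall monotone-trend test with the tie-corrected variance

      S    = sum_{i<j} sgn(x_j - x_i)
      varS = [n(n-1)(2n+5) - sum_g t_g(t_g-1)(2t_g+5)] / 18
      z    = (S -+ 1) / sqrt(varS)   (continuity-corrected, 0 when S = 0)

  with Kendall's tau-b and a two-sided normal p-value;
* the seasonal Mann-Kendall test: the same statistic computed within each
  season (calendar month for monthly data) and summed across seasons,
  without a serial-correlation covariance correction;
* STL decomposition (Cleveland's seasonal-trend decomposition by LOESS,
  additive, exact reconstruction);
* sample autocorrelation with the +-1.96/sqrt(n) white-noise band;
* an FFT periodogram after linear detrending, with dominant-period report;
* a harmonic-regression partial F-test for the presence of seasonality
  (the transparent substitute used here for a full exponential-smoothing
  state-space seasonal model);
* 6-month block moving averages over fixed Oct-Mar / Apr-Sep windows and a
  between-hemisphere opposition score built on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.tsa.seasonal import STL
from statsmodels.tsa.stattools import acf as _sm_acf

from .errors import ConfigError, GranularityError, InsufficientDataError
from .trends_io import MONTHLY, WEEKLY, RSVPanel


# ---------------------------------------------------------------------------
# Mann-Kendall


@dataclass
class MKResult:
    n: int
    S: int
    varS: float
    z: float
    tau: float
    p: float


@dataclass
class SMKResult:
    period: int
    season_S: list[int]
    season_varS: list[float]
    S: int
    varS: float
    z: float
    p: float


def mk_z(S: float, varS: float) -> float:
    """Continuity-corrected normal score for a Mann-Kendall S statistic."""
    if S == 0 or varS <= 0:
        return 0.0
    return (S - 1) / np.sqrt(varS) if S > 0 else (S + 1) / np.sqrt(varS)


def _mk_s_var(x: np.ndarray) -> tuple[int, float, int]:
    """S, tie-corrected varS, and the tie-correction term for tau-b."""
    n = len(x)
    diff = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diff, 1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    tie_var = (ties * (ties - 1) * (2 * ties + 5)).sum() if len(ties) else 0
    varS = (n * (n - 1) * (2 * n + 5) - tie_var) / 18.0
    tie_pairs = int((ties * (ties - 1) // 2).sum()) if len(ties) else 0
    return S, float(varS), tie_pairs


def mann_kendall(x: Sequence[float]) -> MKResult:
    """Mann-Kendall trend test with tie correction and tau-b."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise InsufficientDataError("Mann-Kendall needs at least 3 observations")
    S, varS, tie_pairs = _mk_s_var(x)
    D = n * (n - 1) / 2
    denom = np.sqrt((D - tie_pairs) * D)
    tau = S / denom if denom > 0 else 0.0
    z = mk_z(S, varS)
    p = 2.0 * sps.norm.sf(abs(z))
    return MKResult(n=n, S=S, varS=varS, z=float(z), tau=float(tau), p=float(p))


def _season_index(x, period: int, granularity: str | None) -> np.ndarray:
    if isinstance(x, pd.Series) and isinstance(x.index, pd.DatetimeIndex):
        if granularity == WEEKLY or (granularity is None and period in (52, 53)):
            weeks = x.index.isocalendar().week.to_numpy()
            return np.minimum(weeks, 52) - 1  # ISO week capped at 52
        if period == 12:
            return x.index.month.to_numpy() - 1
    return np.arange(len(x)) % period


def seasonal_mann_kendall(
    x: Sequence[float] | pd.Series,
    period: int = 12,
    granularity: str | None = None,
) -> SMKResult:
    """Seasonal Mann-Kendall: per-season S and varS summed across seasons.

    Date-indexed monthly series are sliced by calendar month; weekly series
    by ISO week-of-year capped at 52; plain arrays by position modulo
    ``period``. No covariance correction for serial correlation is applied.
    """
    if period < 1:
        raise ConfigError("period must be >= 1")
    values = np.asarray(x, dtype=float)
    if len(values) < 3 * period:
        raise InsufficientDataError("need at least 3 full cycles of data")
    seasons = _season_index(x, period, granularity)
    season_S, season_var = [], []
    for s in np.unique(seasons):
        xs = values[seasons == s]
        if len(xs) < 3:
            raise InsufficientDataError(
                f"season {s} has {len(xs)} observations; need >= 3"
            )
        S_i, var_i, _ = _mk_s_var(xs)
        season_S.append(S_i)
        season_var.append(var_i)
    S_tot = int(sum(season_S))
    var_tot = float(sum(season_var))
    z = mk_z(S_tot, var_tot)
    p = 2.0 * sps.norm.sf(abs(z))
    return SMKResult(
        period=period,
        season_S=season_S,
        season_varS=season_var,
        S=S_tot,
        varS=var_tot,
        z=float(z),
        p=float(p),
    )


# ---------------------------------------------------------------------------
# decomposition, autocorrelation, periodogram


@dataclass
class Decomposition:
    seasonal: np.ndarray
    trend: np.ndarray
    remainder: np.ndarray
    period: int


def stl_decompose(
    x: Sequence[float],
    period: int,
    seasonal_span: int = 7,
    trend_span: int | None = None,
    inner: int = 2,
    outer: int = 0,
) -> Decomposition:
    """Additive STL decomposition; seasonal + trend + remainder == x exactly."""
    if period < 2:
        raise ConfigError("period must be >= 2")
    values = np.asarray(x, dtype=float)
    if len(values) < 2 * period:
        raise InsufficientDataError("need at least two full periods")
    res = STL(
        values, period=period, seasonal=seasonal_span, trend=trend_span
    ).fit(inner_iter=inner, outer_iter=outer)
    return Decomposition(
        seasonal=np.asarray(res.seasonal),
        trend=np.asarray(res.trend),
        remainder=np.asarray(res.resid),
        period=period,
    )


def acf(x: Sequence[float], max_lag: int) -> tuple[np.ndarray, float]:
    """Sample autocorrelation and the 95% white-noise significance bound."""
    values = np.asarray(x, dtype=float)
    n = len(values)
    if max_lag >= n:
        raise ConfigError("max_lag must be smaller than the series length")
    if np.ptp(values) == 0:
        raise InsufficientDataError("autocorrelation undefined for a constant series")
    vals = _sm_acf(values, nlags=max_lag, adjusted=False, fft=True)
    return np.asarray(vals), 1.96 / np.sqrt(n)


def periodogram(
    x: Sequence[float], detrend: str = "linear"
) -> tuple[np.ndarray, np.ndarray]:
    """FFT periodogram: (periods, power) at positive Fourier frequencies.

    Power is |X_k|^2 / n. ``detrend`` is "linear", "constant" or None.
    """
    values = np.asarray(x, dtype=float)
    n = len(values)
    if n < 8:
        raise InsufficientDataError("periodogram needs at least 8 observations")
    if detrend in ("linear", "constant"):
        from scipy.signal import detrend as _detrend

        values = _detrend(values, type=detrend)
    elif detrend is not None:
        raise ConfigError(f"unknown detrend mode {detrend!r}")
    spec = np.fft.rfft(values)
    power = (np.abs(spec) ** 2) / n
    k = np.arange(1, len(spec))
    periods = n / k
    return periods, power[1:]


def dominant_periods(
    periods: np.ndarray, power: np.ndarray, m: int = 2
) -> list[float]:
    """The m highest-power periods, strongest first (ties: shorter period)."""
    order = sorted(range(len(power)), key=lambda i: (-power[i], periods[i]))
    return [float(periods[i]) for i in order[:m]]


def seasonality_ftest(
    x: Sequence[float], period: int, harmonics: int = 2, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Partial F-test for seasonal harmonics on top of a linear trend.

    Compares the least-squares fit of intercept + slope + paired sin/cos
    terms at periods ``period/h`` (h = 1..harmonics) against intercept +
    slope alone. Returns (F, p, seasonal) with seasonal = (p < alpha).
    """
    values = np.asarray(x, dtype=float)
    n = len(values)
    if n < 2 * period:
        raise InsufficientDataError("need at least two full periods")
    if period < 2 or 2 * harmonics >= period:
        raise ConfigError("harmonics too high for this period (aliasing)")
    t = np.arange(n, dtype=float)
    X0 = np.column_stack([np.ones(n), t])
    cols = [X0]
    for h in range(1, harmonics + 1):
        w = 2 * np.pi * h * t / period
        cols.append(np.column_stack([np.sin(w), np.cos(w)]))
    X1 = np.hstack(cols)
    q = X1.shape[1] - X0.shape[1]
    rss0 = float(np.sum((values - X0 @ np.linalg.lstsq(X0, values, rcond=None)[0]) ** 2))
    rss1 = float(np.sum((values - X1 @ np.linalg.lstsq(X1, values, rcond=None)[0]) ** 2))
    df_resid = n - X1.shape[1]
    if rss1 <= 0 or df_resid <= 0:
        # a perfect harmonic fit: call it seasonal unless the series is flat
        seasonal = rss0 > 1e-12
        return (np.inf if seasonal else 0.0), (0.0 if seasonal else 1.0), seasonal
    F = ((rss0 - rss1) / q) / (rss1 / df_resid)
    if F <= 0:
        return 0.0, 1.0, False
    p = float(sps.f.sf(F, q, df_resid))
    return float(F), p, p < alpha


# ---------------------------------------------------------------------------
# block moving averages and hemisphere opposition

_MONTH_ABBR = [
    "JAN", "FEB", "MAR", "APR", "MAY", "JUN",
    "JUL", "AUG", "SEP", "OCT", "NOV", "DEC",
]


@dataclass
class BMAResult:
    """Fixed-calendar 6-month block means (Oct-Mar / Apr-Sep by default)."""

    labels: list[str]
    means: np.ndarray
    counts: np.ndarray

    @property
    def partial(self) -> np.ndarray:
        return self.counts < 6

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": self.labels,
                "mean": self.means,
                "n_months": self.counts,
                "partial": self.partial,
            }
        )


def bma(series: pd.Series, anchor_month: int = 10) -> BMAResult:
    """Block moving average over consecutive fixed 6-month calendar windows.

    With the default anchor (October) the windows are Oct-Mar and Apr-Sep;
    partial blocks at the series ends are retained and flagged.
    """
    if not isinstance(series.index, pd.DatetimeIndex):
        raise GranularityError("bma requires a date-indexed monthly series")
    months = series.index.month.to_numpy()
    diffs = series.index.to_period("M")
    if len(series) > 1 and not (np.diff(diffs.asfreq("M").astype(int)) == 1).all():
        raise GranularityError("bma requires consecutive monthly observations")
    if not 1 <= anchor_month <= 12:
        raise ConfigError("anchor_month must be in 1..12")
    start_a = anchor_month  # e.g. 10 -> OCT-MAR
    start_b = (anchor_month + 5) % 12 + 1  # e.g. 4 -> APR-SEP
    lab_a = f"{_MONTH_ABBR[start_a - 1]}-{_MONTH_ABBR[(start_a + 4) % 12]}"
    lab_b = f"{_MONTH_ABBR[start_b - 1]}-{_MONTH_ABBR[(start_b + 4) % 12]}"
    keys = []
    for ts in series.index:
        off = (ts.month - anchor_month) % 12
        if off < 6:
            keys.append((ts.year if ts.month >= anchor_month else ts.year - 1, lab_a))
        else:
            keys.append((ts.year, lab_b))
    frame = pd.DataFrame({"key": keys, "value": series.to_numpy(dtype=float)})
    order, seen = [], set()
    for k in keys:
        if k not in seen:
            order.append(k)
            seen.add(k)
    grouped = frame.groupby("key", sort=False)["value"]
    means = grouped.mean()
    counts = grouped.size()
    labels = [f"{lab} {year}" for (year, lab) in order]
    return BMAResult(
        labels=labels,
        means=np.array([means[k] for k in order]),
        counts=np.array([counts[k] for k in order]),
    )


def hemisphere_opposition(
    panel_a: RSVPanel, panel_b: RSVPanel, anchor_month: int = 10
) -> float:
    """Fraction of aligned 6-month blocks where the two regions' search
    interest deviates from its own mean in opposite directions.

    1.0 means perfectly juxtaposed (anti-phase) seasonal patterns, 0.0
    identical ones; independent panels sit near 0.5.
    """
    if panel_a.granularity != MONTHLY or panel_b.granularity != MONTHLY:
        raise GranularityError("hemisphere comparison needs monthly panels")
    if set(panel_a.terms) != set(panel_b.terms):
        raise ConfigError("panels must cover the same terms")
    opposed = total = 0
    for term in sorted(panel_a.terms):
        ra = bma(panel_a.series(term), anchor_month=anchor_month)
        rb = bma(panel_b.series(term), anchor_month=anchor_month)
        common = [lab for lab in ra.labels if lab in set(rb.labels)]
        if not common:
            continue
        ia = {lab: i for i, lab in enumerate(ra.labels)}
        ib = {lab: i for i, lab in enumerate(rb.labels)}
        dev_a = np.array([ra.means[ia[lab]] for lab in common])
        dev_b = np.array([rb.means[ib[lab]] for lab in common])
        dev_a = dev_a - dev_a.mean()
        dev_b = dev_b - dev_b.mean()
        opposed += int(np.sum(dev_a * dev_b < 0))
        total += len(common)
    if total == 0:
        raise InsufficientDataError("no overlapping blocks between the panels")
    return opposed / total
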