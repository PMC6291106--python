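"""Trend and seasonality statistics against brute-force oracles."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from scld import seasonality, synthetic
from scld.errors import ConfigError, GranularityError, InsufficientDataError
from scld.trends_io import RSVPanel


def brute_mk(x):
    """O(n^2) pairwise-sign oracle for S and the tie-corrected variance."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    S = sum(
        np.sign(x[j] - x[i]) for i in range(n) for j in range(i + 1, n)
    )
    ties = [c for c in Counter(x).values() if c > 1]
    tie_term = sum(t * (t - 1) * (2 * t + 5) for t in ties)
    varS = (n * (n - 1) * (2 * n + 5) - tie_term) / 18
    return int(S), varS


class TestMannKendall:
    def test_strictly_increasing_short_series(self):
        r = seasonality.mann_kendall([1, 2, 3, 4])
        assert r.S == 6
        assert r.tau == pytest.approx(1.0)
        assert r.varS == pytest.approx(8.667, abs=5e-4)
        assert r.p < 0.1

    def test_matches_brute_force_on_random_series_with_ties(self, rng):
        for _ in range(40):
            n = int(rng.integers(5, 31))
            x = rng.integers(0, 6, size=n).astype(float)
            r = seasonality.mann_kendall(x)
            S, varS = brute_mk(x)
            assert r.S == S
            assert r.varS == pytest.approx(varS)
            assert abs(r.S) <= n * (n - 1) / 2

    def test_constant_series_has_zero_z(self):
        r = seasonality.mann_kendall([5.0] * 10)
        assert r.S == 0 and r.z == 0.0 and r.varS == 0.0

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            seasonality.mann_kendall([1, 2])

    def test_tau_matches_scipy_kendalltau(self, rng):
        from scipy.stats import kendalltau

        for _ in range(10):
            x = rng.integers(0, 8, size=25).astype(float)
            r = seasonality.mann_kendall(x)
            expected = kendalltau(np.arange(len(x)), x).statistic
            assert r.tau == pytest.approx(expected)


class TestZConvention:
    """Continuity-corrected z reconstructed from published (S, varS) pairs."""

    @pytest.mark.parametrize(
        "S,varS,z_printed",
        [
            (-5274, 431995, -8.02),
            (-8440, 433651, -12.81),
            (-7500, 432005, -11.40),
            (-465, 3108, -8.32),
            (-767, 3122, -13.71),
            (-917, 3215, -16.16),
            (-669, 3108, -11.98),
            (2144, 424894, 3.29),
            (-808, 424478, -1.24),
        ],
    )
    def test_reproduces_printed_z_to_last_digit(self, S, varS, z_printed):
        # printed variances are integer-rounded, so agreement is asserted to
        # one unit in the last printed decimal
        assert seasonality.mk_z(S, varS) == pytest.approx(z_printed, abs=0.01)


class TestSeasonalMannKendall:
    def test_equals_per_month_brute_force(self, rng):
        for _ in range(15):
            x = rng.integers(0, 50, size=60).astype(float)  # 5 years monthly
            r = seasonality.seasonal_mann_kendall(x, period=12)
            S_tot, var_tot = 0, 0.0
            for m in range(12):
                S, varS = brute_mk(x[m::12])
                S_tot += S
                var_tot += varS
            assert r.S == S_tot
            assert r.varS == pytest.approx(var_tot)
            assert r.S == sum(r.season_S)
            assert r.varS == pytest.approx(sum(r.season_varS))

    def test_months_constant_across_years_give_zero(self):
        x = np.tile(np.arange(12, dtype=float), 3)
        r = seasonality.seasonal_mann_kendall(x, period=12)
        assert r.S == 0 and r.z == 0.0

    def test_reduces_to_mk_when_period_is_one(self, rng):
        x = rng.normal(size=30)
        smk = seasonality.seasonal_mann_kendall(x, period=1)
        mk = seasonality.mann_kendall(x)
        assert smk.S == mk.S
        assert smk.varS == pytest.approx(mk.varS)
        assert smk.z == pytest.approx(mk.z)

    def test_calendar_month_slicing_on_datetime_index(self):
        idx = pd.date_range("2004-01-01", periods=48, freq="MS")
        x = pd.Series(np.arange(48, dtype=float), index=idx)
        r = seasonality.seasonal_mann_kendall(x, period=12)
        # within each month the 4 yearly values strictly increase: S = 6 * 12
        assert r.S == 72

    def test_insufficient_cycles_rejected(self):
        with pytest.raises(InsufficientDataError):
            seasonality.seasonal_mann_kendall(np.arange(30), period=12)


class TestStl:
    def test_additive_identity_is_exact(self, rng):
        x = rng.normal(50, 10, size=72)
        d = seasonality.stl_decompose(x, period=12)
        np.testing.assert_allclose(d.seasonal + d.trend + d.remainder, x, atol=1e-9)

    def test_pure_cosine_has_negligible_remainder(self):
        t = np.arange(156)
        amp = 10.0
        x = amp * np.cos(2 * np.pi * t / 12)
        d = seasonality.stl_decompose(x, period=12)
        assert np.abs(d.remainder).max() < 1e-6 * amp

    def test_constant_series_splits_into_flat_components(self):
        d = seasonality.stl_decompose(np.full(48, 7.0), period=12)
        assert np.abs(d.seasonal).max() < 1e-8
        np.testing.assert_allclose(d.trend, 7.0, atol=1e-8)

    def test_adding_constant_shifts_only_the_trend(self, rng):
        x = rng.normal(0, 1, size=96) + 5 * np.cos(2 * np.pi * np.arange(96) / 12)
        a = seasonality.stl_decompose(x, period=12)
        b = seasonality.stl_decompose(x + 100.0, period=12)
        np.testing.assert_allclose(a.seasonal, b.seasonal, atol=1e-6)
        np.testing.assert_allclose(b.trend - a.trend, 100.0, atol=1e-6)

    def test_bad_period_rejected(self):
        with pytest.raises(ConfigError):
            seasonality.stl_decompose(np.arange(30.0), period=1)


class TestAcf:
    def test_lag_zero_is_one(self, rng):
        vals, bound = seasonality.acf(rng.normal(size=100), max_lag=10)
        assert vals[0] == pytest.approx(1.0)
        assert bound == pytest.approx(1.96 / 10.0)

    def test_cosine_has_local_maxima_at_multiples_of_its_period(self):
        x = np.cos(2 * np.pi * np.arange(240) / 6)
        vals, _ = seasonality.acf(x, max_lag=24)
        for lag in (6, 12, 18, 24):
            assert vals[lag] > vals[lag - 2]
            assert vals[lag] > vals[(lag + 2) % 25]

    def test_white_noise_exceedance_rate_near_nominal(self):
        rates = []
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=500)
            vals, bound = seasonality.acf(x, max_lag=100)
            rates.append(np.mean(np.abs(vals[1:]) > bound))
        assert np.mean(rates) <= 0.10

    def test_constant_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            seasonality.acf(np.ones(50), max_lag=5)


class TestPeriodogram:
    def test_semiannual_tone_dominates(self):
        x = np.cos(2 * np.pi * np.arange(156) / 6)
        periods, power = seasonality.periodogram(x)
        assert seasonality.dominant_periods(periods, power, 1) == [6.0]

    def test_two_tones_rank_six_then_three(self):
        t = np.arange(156)
        x = 2 * np.cos(2 * np.pi * t / 6) + np.cos(2 * np.pi * t / 3)
        periods, power = seasonality.periodogram(x)
        assert seasonality.dominant_periods(periods, power, 2) == [6.0, 3.0]

    def test_matches_direct_dft_sum(self, rng):
        x = rng.normal(size=64)
        periods, power = seasonality.periodogram(x, detrend=None)
        n = len(x)
        for k in (1, 5, 17, 32):
            direct = abs(sum(x[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n)))
            assert power[k - 1] == pytest.approx(direct**2 / n, rel=1e-8)

    def test_invariant_to_additive_constant(self, rng):
        x = rng.normal(size=120)
        _, p1 = seasonality.periodogram(x)
        _, p2 = seasonality.periodogram(x + 1000.0)
        np.testing.assert_allclose(p1, p2, atol=1e-6)

    def test_parseval_total_power_on_mean_removed_input(self, rng):
        x = rng.normal(size=128)
        x = x - x.mean()
        periods, power = seasonality.periodogram(x, detrend=None)
        # rfft accounting: interior bins count twice, Nyquist once
        total = 2 * power[:-1].sum() + power[-1]
        assert total == pytest.approx((x**2).sum(), rel=1e-10)


class TestSeasonalityFtest:
    def test_detects_planted_strong_seasonality(self):
        t = np.arange(156)
        hits = 0
        for seed in range(20):
            noise = np.random.default_rng(seed).normal(0, 3, 156)
            x = 50 + 8 * np.cos(2 * np.pi * t / 6) + noise
            _, _, seasonal = seasonality.seasonality_ftest(x, period=12)
            hits += seasonal
        assert hits == 20

    def test_constant_series_is_not_seasonal(self):
        F, p, seasonal = seasonality.seasonality_ftest(np.full(48, 3.0), period=12)
        assert F == 0.0 and not seasonal

    def test_excessive_harmonics_rejected(self):
        with pytest.raises(ConfigError):
            seasonality.seasonality_ftest(np.arange(48.0), period=4, harmonics=2)


class TestBma:
    def monthly(self, values, start="2004-01-01"):
        idx = pd.date_range(start, periods=len(values), freq="MS")
        return pd.Series(np.asarray(values, dtype=float), index=idx)

    def test_constant_series_blocks_all_equal(self):
        r = seasonality.bma(self.monthly(np.full(156, 50.0)))
        np.testing.assert_allclose(r.means, 50.0)

    def test_alternating_halves_split_cleanly(self):
        # Apr-Sep at 0, Oct-Mar at 100, starting in April
        values = [0] * 6 + [100] * 6
        r = seasonality.bma(self.monthly(values, start="2004-04-01"))
        assert set(np.round(r.means, 6)) == {0.0, 100.0}
        assert r.labels[0].startswith("APR-SEP")

    def test_matches_slice_mean_oracle(self, rng):
        values = rng.uniform(0, 100, size=60)
        series = self.monthly(values)
        r = seasonality.bma(series)
        for label, mean in zip(r.labels, r.means):
            window, year = label.split(" ")
            months = (
                [10, 11, 12, 1, 2, 3] if window == "OCT-MAR" else [4, 5, 6, 7, 8, 9]
            )
            mask = []
            for ts in series.index:
                block_year = (
                    ts.year
                    if (window == "APR-SEP" or ts.month >= 10)
                    else ts.year - 1
                )
                mask.append(ts.month in months and block_year == int(year))
            assert mean == pytest.approx(series[np.array(mask)].mean())

    def test_partial_end_blocks_flagged(self):
        r = seasonality.bma(self.monthly(np.arange(14.0)))  # Jan 2004 - Feb 2005
        assert r.partial[0]  # leading Jan-Mar stub of the Oct 2003 block
        assert r.partial[-1]

    def test_weekly_input_rejected(self):
        idx = pd.date_range("2004-01-04", periods=20, freq="7D")
        with pytest.raises(GranularityError):
            seasonality.bma(pd.Series(np.ones(20), index=idx))


class TestHemisphereOpposition:
    def annual_panel(self, phase_offset=0.0, seed=0, noise_sd=0.0):
        cp = synthetic.DiseaseClassParams(60, 0.0, 0.0, 10.0)
        cfg = synthetic.SyntheticConfig(
            seed=seed,
            noise_sd=noise_sd,
            class_params={k: cp for k in synthetic.LABELS},
        )
        return synthetic.gen_panel(cfg, phase_offset=phase_offset)

    def test_antiphase_panels_score_one(self):
        a = self.annual_panel()
        b = self.annual_panel(phase_offset=np.pi)
        assert seasonality.hemisphere_opposition(a, b) == 1.0

    def test_identical_panels_score_zero(self):
        a = self.annual_panel()
        assert seasonality.hemisphere_opposition(a, a) == 0.0

    def test_independent_panels_score_near_half(self):
        fractions = []
        idx = pd.date_range("2004-01-01", periods=60, freq="MS")
        for seed in range(50):
            g = np.random.default_rng(seed)
            frames = []
            for _ in range(2):
                frames.append(
                    pd.DataFrame(
                        {"d1": g.uniform(0, 100, 60), "d2": g.uniform(0, 100, 60)},
                        index=idx,
                    )
                )
            pa = RSVPanel(frame=frames[0], geo="A", granularity="monthly")
            pb = RSVPanel(frame=frames[1], geo="B", granularity="monthly")
            fractions.append(seasonality.hemisphere_opposition(pa, pb))
        assert 0.4 < np.mean(fractions) < 0.6

    def test_mismatched_terms_rejected(self):
        a = self.annual_panel()
        b = RSVPanel(
            frame=a.frame.rename(columns={"asthma": "other"}),
            geo="B",
            granularity="monthly",
        )
        with pytest.raises(ConfigError):
            seasonality.hemisphere_opposition(a, b)
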