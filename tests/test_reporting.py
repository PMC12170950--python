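"""Aggregation, agreement statistics, and report-export tests."""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posturekit import (
    aggregate_minutes,
    export_report,
    mape,
    pearson_with_band,
    validate_series,
)
from posturekit.errors import EmptySessionError, UndefinedCorrelationError
from posturekit.reporting import CorrelationBand, histogram_counts


def quartile_oracle(values, q):
    """Brute-force order-statistic interpolation (type 7)."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    if lo + 1 >= len(v):
        return v[-1]
    return v[lo] + (h - lo) * (v[lo + 1] - v[lo])


def exact_r_series(r, n=60, seed=3):
    """Construct paired series whose sample Pearson r is exactly `r`."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= x * (x @ z) / (x @ x)  # orthogonalize
    z /= z.std()
    y = r * x + math.sqrt(1 - r * r) * z
    return x, y


class TestAggregateMinutes:
    def frame(self, t, **channels):
        return pd.DataFrame({"t_s": t, **channels})

    def test_constant_series_collapses(self):
        df = self.frame(np.arange(120.0), ca_deg=np.full(120, 40.0))
        aggs = aggregate_minutes(df)
        assert len(aggs) == 2
        for a in aggs:
            assert (a.min, a.q1, a.median, a.q3, a.max) == (40.0,) * 5
            assert a.n == 60

    def test_first_sixty_integers(self):
        df = self.frame(np.arange(60.0), ca_deg=np.arange(1.0, 61.0))
        (agg,) = aggregate_minutes(df)
        assert agg.median == pytest.approx(30.5)
        assert agg.q1 == pytest.approx(15.75)
        assert agg.q3 == pytest.approx(45.25)

    def test_protocol_length_gives_four_minutes(self):
        df = self.frame(np.arange(240.0), ca_deg=np.random.default_rng(0).uniform(30, 60, 240))
        assert len(aggregate_minutes(df)) == 4

    def test_absent_samples_excluded_from_n(self):
        values = np.full(60, 45.0)
        values[10:20] = np.nan
        (agg,) = aggregate_minutes(self.frame(np.arange(60.0), ka_deg=values))
        assert agg.n == 50

    def test_quartiles_match_sort_oracle(self):
        rng = np.random.default_rng(7)
        for n in (1, 2, 3, 5, 17, 59, 60):
            values = rng.uniform(0, 90, n)
            (agg,) = aggregate_minutes(self.frame(np.arange(float(n)), ca_deg=values))
            assert agg.q1 == pytest.approx(quartile_oracle(values, 0.25), abs=1e-12)
            assert agg.median == pytest.approx(quartile_oracle(values, 0.5), abs=1e-12)
            assert agg.q3 == pytest.approx(quartile_oracle(values, 0.75), abs=1e-12)
            assert agg.min <= agg.q1 <= agg.median <= agg.q3 <= agg.max


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        stats = pearson_with_band(x, 2 * x + 1)
        assert stats.r == pytest.approx(1.0)
        assert stats.r_band is CorrelationBand.VERY_HIGH
        assert stats.r_squared_pct == pytest.approx(100.0)

    def test_negative_r_banded_by_magnitude(self):
        x = np.arange(10.0)
        stats = pearson_with_band(x, -x)
        assert stats.r == pytest.approx(-1.0)
        assert stats.r_band is CorrelationBand.VERY_HIGH

    @pytest.mark.parametrize(
        "r, band",
        [
            (0.992, CorrelationBand.VERY_HIGH),
            (0.90, CorrelationBand.VERY_HIGH),
            (0.809, CorrelationBand.HIGH),
            (0.704, CorrelationBand.HIGH),
            (0.70, CorrelationBand.HIGH),
            (0.607, CorrelationBand.MODERATE),
            (0.50, CorrelationBand.MODERATE),
            (0.49, CorrelationBand.LOW),
        ],
    )
    def test_band_cutpoints(self, r, band):
        x, y = exact_r_series(r)
        stats = pearson_with_band(x, y)
        assert stats.r == pytest.approx(r, abs=1e-12)
        assert stats.r_band is band

    def test_matches_covariance_oracle(self):
        """r agrees with a from-scratch covariance/variance formula to 1e-12."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            x = rng.uniform(0, 90, 1000)
            y = 0.6 * x + rng.uniform(0, 30, 1000)
            xc, yc = x - x.mean(), y - y.mean()
            oracle = float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))
            assert pearson_with_band(x, y).r == pytest.approx(oracle, abs=1e-12)

    def test_p_value_matches_t_transform(self):
        from scipy.stats import t as tdist

        x, y = exact_r_series(0.704, n=120)
        stats = pearson_with_band(x, y)
        t_stat = stats.r * math.sqrt((stats.n - 2) / (1 - stats.r**2))
        expected = 2 * tdist.sf(abs(t_stat), stats.n - 2)
        assert stats.p_two_tailed == pytest.approx(expected, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_band([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_series_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_band([1.0, 2.0], [1.0, 2.0])


class TestMape:
    def test_identical_series_is_zero(self):
        assert mape([40.0, 50.0], [40.0, 50.0]) == 0.0

    def test_acceptance_boundary_case(self):
        assert mape([100.0, 100.0], [95.0, 105.0]) == pytest.approx(0.05)

    def test_single_pair(self):
        assert mape([40.0], [44.0]) == pytest.approx(0.10)

    def test_zero_reference_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            value = mape([0.0, 100.0], [5.0, 110.0])
        assert value == pytest.approx(0.10)
        assert "zero reference" in caplog.text

    def test_all_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            mape([0.0, 0.0], [1.0, 2.0])

    @given(k=st.floats(0.001, 1000))
    @settings(max_examples=100)
    def test_scale_invariance(self, k):
        ref = np.array([40.0, 55.0, 20.0, 45.0])
        cand = np.array([41.0, 54.0, 21.0, 47.0])
        assert mape(k * ref, k * cand) == pytest.approx(mape(ref, cand), rel=1e-9)


class TestHistogram:
    def test_constant_series_single_bin(self):
        h = histogram_counts([40.0] * 30)
        assert (h["count"] > 0).sum() == 1
        assert h["count"].sum() == 30

    def test_one_degree_bins(self):
        h = histogram_counts([40.2, 40.7, 41.5])
        assert h["bin_right"].iloc[0] - h["bin_left"].iloc[0] == pytest.approx(1.0)
        assert list(h["count"]) == [2, 1]


class TestExportReport:
    def test_simulated_protocol_report_structure(self, tmp_path):
        from posturekit.classify import summarize_session
        from posturekit.session import SessionSeries
        from tests.test_classification import Angles

        series = SessionSeries(
            samples=[Angles(t=float(t), ca_deg=40.0 if t < 120 else 55.0,
                            ka_deg=45.0 if t < 120 else 20.0)
                     for t in range(240)]
        )
        summary = summarize_session(series)
        df = pd.DataFrame({
            "t_s": np.arange(240.0),
            "ca_deg": [s.ca_deg for s in series],
            "ka_deg": [s.ka_deg for s in series],
        })
        aggs = aggregate_minutes(df)
        stats = {"ca": validate_series(df["ca_deg"], df["ca_deg"] + 0.5)}
        written = export_report(summary, aggs, stats, tmp_path, series=df, plots=True)
        report = json.loads(written["report"].read_text())
        assert report["summary"]["n_samples"] == 240
        assert report["agreement"]["ca"]["mape"] > 0
        assert report["quartile_method"] == "linear"
        minutes = pd.read_csv(written["minutes"])
        for channel in ("ca_deg", "ka_deg"):
            assert (minutes["channel"] == channel).sum() == 4
        assert written["trace_plot"].exists()
        assert written["histogram"].exists()

    def test_empty_session_rejected(self, tmp_path):
        with pytest.raises(EmptySessionError):
            export_report(None, [], None, tmp_path)
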