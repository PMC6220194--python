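"""Tests of normalization, budding correction, condition summaries, model/results."""

import math

import numpy as np
import pandas as pd
import pytest

from padflux.detection import WindowCount, count_peaks_in_windows
from padflux.growth import (
    AnalysisUnitMeta,
    GrowthRateModel,
    PeakRateSeries,
    condition_summary,
    correct_for_budding,
    normalize_peak_rate,
    relative_change,
    segment_by_condition,
)
from padflux.media import MediaSchedule
from padflux.synthetic import ColonyParams, simulate_colony


def _meta(unit="u", start=500.0, end=500.0, pads=3):
    return AnalysisUnitMeta(
        unit_id=unit, chamber_id="c", pads_filled=pads, cell_count_start=start, cell_count_end=end
    )


def _series(rates, unit="u", condition=None, start=0.0, length=240.0):
    rates = np.asarray(rates, dtype=float)
    starts = start + np.arange(rates.size) * length
    return PeakRateSeries(unit, condition, starts, np.full(rates.size, length), rates)


def _simulated_series(rate_per_h, capacity, hours, seed, window=240.0):
    """Event-level simulated unit: counts windowed, normalized with exact N."""
    p = ColonyParams(growth_rate_per_cell=rate_per_h, pad_capacity=capacity)
    sim = simulate_colony(p, hours * 3600.0, seed=seed)
    counts = count_peaks_in_windows(sim.events.times, window, (0.0, hours * 3600.0), unit_id="u")
    return normalize_peak_rate(counts, _meta(start=capacity, end=capacity))


class TestNormalizePeakRate:
    def test_forced_arithmetic(self):
        counts = [WindowCount("u", 0.0, 240.0, 24)]
        series = normalize_peak_rate(counts, _meta(start=500, end=500))
        assert series.rates[0] == pytest.approx(24 / (500 * (240 / 3600)))  # 0.72/h

    def test_zero_count_zero_rate(self):
        series = normalize_peak_rate([WindowCount("u", 0.0, 240.0, 0)], _meta())
        assert series.rates[0] == 0.0

    def test_start_end_counts_averaged(self):
        counts = [WindowCount("u", 0.0, 240.0, 24)]
        series = normalize_peak_rate(counts, _meta(start=400, end=600))  # mean 500
        assert series.rates[0] == pytest.approx(0.72)

    def test_zero_cell_count_not_normalizable(self):
        with pytest.raises(ValueError, match="not normalizable"):
            normalize_peak_rate([WindowCount("u", 0.0, 240.0, 1)], _meta(start=0, end=0))

    def test_variable_window_lengths_each_normalized_by_own(self):
        counts = [WindowCount("u", 0.0, 240.0, 24), WindowCount("u", 240.0, 120.0, 12)]
        series = normalize_peak_rate(counts, _meta(start=500, end=500))
        assert series.rates[0] == pytest.approx(series.rates[1])

    def test_parameter_recovery_on_simulated_unit(self):
        # per-cell rate 0.288/h, capacity 400, 90 four-minute windows
        series = _simulated_series(0.288, 400, hours=6.0, seed=100)
        assert len(series) >= 80
        mean = series.rates.mean()
        sem = series.rates.std(ddof=1) / math.sqrt(len(series))
        assert abs(mean - 0.288) < 2 * sem


class TestBuddingCorrection:
    def test_identity_at_zero(self):
        assert correct_for_budding(0.288, 0.0) == pytest.approx(0.288)

    def test_forced_arithmetic(self):
        assert correct_for_budding(0.288, 0.6) == pytest.approx(0.4608)

    def test_facs_budding_index(self):
        assert correct_for_budding(1.0, 0.68) == pytest.approx(1.68)

    @pytest.mark.parametrize("bi", [-0.1, 1.1])
    def test_out_of_range_rejected(self, bi):
        with pytest.raises(ValueError):
            correct_for_budding(0.3, bi)


class TestSegmentByCondition:
    def test_single_condition_identity(self):
        series = _series([0.1, 0.2, 0.3], condition=None)
        media = MediaSchedule([(0.0, "YPD")])
        (out,) = segment_by_condition(series, media)
        assert out.condition == "YPD"
        assert np.array_equal(out.rates, series.rates)

    def test_switch_window_dropped_rest_assigned(self):
        # 240 s windows over [0, 72000); switch at 36000 s, buffer 40 s
        n = 300
        series = _series(np.linspace(0.1, 0.4, n))
        media = MediaSchedule([(0.0, "A"), (36000.0, "B")], switch_duration=40.0)
        parts = segment_by_condition(series, media, buffer=40.0)
        assert [p.condition for p in parts] == ["A", "B"]
        a, b = parts
        # brute-force assignment oracle
        for i in range(n):
            ws, we = 240.0 * i, 240.0 * (i + 1)
            if ws < 36040.0 and we > 35960.0:
                assert ws not in a.window_starts and ws not in b.window_starts
            elif we <= 36000.0:
                assert ws in a.window_starts
            else:
                assert ws in b.window_starts
        # the window containing the switch and the one ending at it both touch
        # the +/-40 s guard band, so exactly those two are dropped
        assert len(a) + len(b) == n - 2
        assert 36000.0 not in a.window_starts and 36000.0 not in b.window_starts

    def test_all_windows_in_buffer_warns_and_empty(self):
        series = _series([0.1], start=35900.0, length=240.0)
        media = MediaSchedule([(0.0, "A"), (36000.0, "B")])
        with pytest.warns(UserWarning, match="switch buffer"):
            parts = segment_by_condition(series, media, buffer=40.0)
        assert parts == []

    def test_repeated_condition_pooled(self):
        series = _series([0.3] * 10, length=100.0)
        media = MediaSchedule([(0.0, "A"), (400.0, "B"), (700.0, "A")], switch_duration=0.0)
        parts = segment_by_condition(series, media, buffer=0.0)
        labels = [p.condition for p in parts]
        assert labels == ["A", "B"]
        assert len(parts[0]) == 4 + 3  # windows from both A phases pooled


class TestConditionSummary:
    def test_equal_values_zero_sem(self):
        est = condition_summary(_series([0.3, 0.3, 0.3]), budding_index=0.0)
        assert est.mean_peak_rate == pytest.approx(0.3)
        assert est.sem_peak_rate == 0.0

    def test_textbook_mean_sem(self):
        est = condition_summary(_series([0.2, 0.3, 0.4]), budding_index=0.0)
        assert est.mean_peak_rate == pytest.approx(0.3)
        assert est.sem_peak_rate == pytest.approx(0.1 / math.sqrt(3))

    def test_budding_correction_applied(self):
        est = condition_summary(_series([0.2, 0.3, 0.4]), budding_index=0.6)
        assert est.growth_rate == pytest.approx(0.3 * 1.6)
        assert est.sem_growth_rate == pytest.approx(est.sem_peak_rate * 1.6)

    def test_single_window_sem_flagged(self):
        est = condition_summary(_series([0.3]), budding_index=0.6)
        assert est.n_windows == 1
        assert est.sem_peak_rate == 0.0
        assert not est.sem_defined

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            condition_summary(_series([]), budding_index=0.6)

    def test_calcium_truth_recovered_within_two_sem(self):
        # vph1-delta-like: true per-cell rate 0.196/h under calcium
        series = _simulated_series(0.196, 400, hours=10.0, seed=200)
        est = condition_summary(series, budding_index=0.6)
        assert abs(est.mean_peak_rate - 0.196) < 2 * est.sem_peak_rate


class TestRelativeChange:
    def test_no_change(self):
        assert relative_change(0.3, 0.3) == 0.0

    def test_printed_pairs(self):
        assert relative_change(0.196, 0.32) == pytest.approx(63.27, abs=0.01)
        assert relative_change(0.25, 0.30) == pytest.approx(20.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_change(0.0, 0.3)


class TestInvariants:
    def test_normalization_cancels_colony_size(self):
        # same per-cell rate, different capacities (2 vs 3 filled pads)
        a = _simulated_series(0.288, 800, hours=6.0, seed=300)
        b = _simulated_series(0.288, 1200, hours=6.0, seed=301)
        ea = condition_summary(a, 0.0)
        eb = condition_summary(b, 0.0)
        tol = 3 * math.hypot(ea.sem_peak_rate, eb.sem_peak_rate)
        assert abs(ea.mean_peak_rate - eb.mean_peak_rate) < tol

    def test_unbiasedness_over_many_runs(self):
        # mean recovered rate over >=200 event-level runs within 1% of truth
        master = np.random.SeedSequence(777)
        p = ColonyParams(growth_rate_per_cell=0.288, pad_capacity=400)
        means = []
        for s in master.spawn(500):
            sim = simulate_colony(p, 6 * 3600.0, seed=s)
            counts = count_peaks_in_windows(sim.events.times, 240.0, (0.0, 6 * 3600.0), unit_id="u")
            series = normalize_peak_rate(counts, _meta(start=400, end=400))
            means.append(series.rates.mean())
        assert abs(np.mean(means) - 0.288) / 0.288 < 0.01

    def test_window_length_scale_equivariance(self):
        # doubling the window halves the per-window rate variance, mean unchanged
        p = ColonyParams(growth_rate_per_cell=0.36, pad_capacity=1000)
        sim = simulate_colony(p, 48000.0, seed=888)
        meta = _meta(start=1000, end=1000)
        s1 = normalize_peak_rate(
            count_peaks_in_windows(sim.events.times, 240.0, (0.0, 48000.0), unit_id="u"), meta
        )
        s2 = normalize_peak_rate(
            count_peaks_in_windows(sim.events.times, 480.0, (0.0, 48000.0), unit_id="u"), meta
        )
        ratio = s1.rates.var(ddof=1) / s2.rates.var(ddof=1)
        assert 1.4 < ratio < 2.8
        tol = 3 * math.hypot(
            s1.rates.std(ddof=1) / math.sqrt(len(s1)), s2.rates.std(ddof=1) / math.sqrt(len(s2))
        )
        assert abs(s1.rates.mean() - s2.rates.mean()) < tol

    def test_printed_precision_rounding(self):
        assert f"{relative_change(0.196, 0.32):.0f}" == "63"
        assert f"{relative_change(0.25, 0.30):.0f}" == "20"
        assert f"{0.287951:.3f}" == "0.288"


class TestGrowthRateModel:
    def _counts(self):
        rng = np.random.default_rng(0)
        counts = []
        for unit, nbar in [("u1", 500.0), ("u2", 750.0)]:
            lam = 0.3 * nbar / 3600.0  # same per-cell rate
            for i in range(30):
                counts.append(WindowCount(unit, 240.0 * i, 240.0, int(rng.poisson(lam * 240.0))))
        meta = {
            "u1": _meta("u1", 500, 500),
            "u2": _meta("u2", 750, 750),
        }
        return counts, meta

    def test_fit_returns_per_unit_estimates(self):
        counts, meta = self._counts()
        res = GrowthRateModel(counts, meta, budding_index=0.6).fit()
        assert {e.unit_id for e in res.estimates} == {"u1", "u2"}
        for e in res.estimates:
            assert abs(e.mean_peak_rate - 0.3) < 4 * e.sem_peak_rate
            assert e.growth_rate == pytest.approx(e.mean_peak_rate * 1.6)

    def test_from_dataframe_roundtrip(self):
        counts, meta = self._counts()
        cdf = pd.DataFrame(
            {
                "unit_id": [c.unit_id for c in counts],
                "window_start_s": [c.start for c in counts],
                "window_length_s": [c.length for c in counts],
                "count": [c.count for c in counts],
            }
        )
        mdf = pd.DataFrame(
            {
                "unit_id": ["u1", "u2"],
                "chamber_id": ["c", "c"],
                "pads_filled": [3, 3],
                "cell_count_start": [500.0, 750.0],
                "cell_count_end": [500.0, 750.0],
            }
        )
        res_a = GrowthRateModel(counts, meta).fit()
        res_b = GrowthRateModel.from_dataframe(cdf, mdf).fit()
        pd.testing.assert_frame_equal(res_a.to_frame(), res_b.to_frame())

    def test_media_segmentation_and_relative_changes(self):
        rng = np.random.default_rng(1)
        media = MediaSchedule([(0.0, "YPD"), (14400.0, "YPD+Ca")], switch_duration=40.0)
        counts = []
        for i in range(120):
            start = 240.0 * i
            rate = 0.32 if start + 240.0 <= 14400.0 else 0.196
            lam = rate * 500 / 3600.0
            counts.append(WindowCount("u1", start, 240.0, int(rng.poisson(lam * 240.0))))
        model = GrowthRateModel(counts, {"u1": _meta("u1")}, media=media, budding_index=0.6)
        res = model.fit()
        assert [e.condition for e in res.estimates] == ["YPD", "YPD+Ca"]
        changes = res.relative_changes()
        assert len(changes) == 1
        row = changes.iloc[0]
        assert row.reference_condition == "YPD+Ca"  # slower condition is the reference
        assert row.relative_change_percent > 0

    def test_summary_text(self):
        counts, meta = self._counts()
        res = GrowthRateModel(counts, meta, budding_index=0.6).fit()
        text = res.summary()
        assert "budding index: 0.60" in text
        assert "u1" in text and "u2" in text

    def test_missing_metadata_rejected(self):
        counts, _ = self._counts()
        with pytest.raises(ValueError, match="without metadata"):
            GrowthRateModel(counts, {"u1": _meta("u1")})
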