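import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recoverews import (CompositeMetric, DetectionConfig, composite_metric,
                        consecutive_filter, detect_signals,
                        enumerate_metric_combinations, max_consecutive_run,
                        max_signal_strength, metric_name, normalize_running)
from recoverews.indicators import IndicatorSeries


def raw(values, start=2000, ind="CV"):
    values = np.asarray(values, dtype=float)
    return IndicatorSeries(ind, np.arange(start, start + values.size), values)


class TestNormalization:
    def test_worked_example(self):
        nz = normalize_running(raw([1, 2, 3]))
        assert np.isnan(nz.values[0])
        assert nz.values[1] == pytest.approx(1 / np.sqrt(2), abs=1e-10)
        assert nz.values[1] == pytest.approx(0.7071, abs=1e-4)
        assert nz.values[2] == pytest.approx(1.0)

    def test_constant_series_degenerate_zero(self):
        nz = normalize_running(raw([5, 5, 5, 5]))
        np.testing.assert_array_equal(nz.values[1:], 0.0)
        assert np.all(nz.degenerate[1:])

    def test_undefined_before_second_value(self):
        nz = normalize_running(raw([3, 1, 4]))
        assert np.isnan(nz.values[0])

    def test_interior_missing_values_skipped(self):
        nz = normalize_running(raw([1, np.nan, 2, 3]))
        assert np.isnan(nz.values[1])
        # running stats at t=3 use {1, 2, 3}
        assert nz.values[3] == pytest.approx((3 - 2.0) / 1.0)

    def test_matches_direct_evaluation_oracle(self, rng):
        for _ in range(300):
            x = rng.normal(size=rng.integers(2, 40))
            nz = normalize_running(raw(x))
            for t in range(1, x.size):
                w = x[:t + 1]
                expected = (x[t] - w.mean()) / w.std(ddof=1)
                assert nz.values[t] == pytest.approx(expected, abs=1e-10)


class TestCombinations:
    def test_four_indicators_give_fifteen_metrics(self):
        subs = enumerate_metric_combinations()
        assert len(subs) == 15
        assert len(set(subs)) == 15

    def test_singleton(self):
        assert enumerate_metric_combinations(["CV"]) == [("CV",)]

    def test_three_indicators_brute_force_count(self):
        # 2^3 - 1 non-empty subsets
        subs = enumerate_metric_combinations(["AR1", "CV", "SD_SIZE"])
        assert len(subs) == 7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            enumerate_metric_combinations([])

    def test_headline_metric_names(self):
        names = [metric_name(m) for m in enumerate_metric_combinations()]
        assert "AR(1) + SD size" in names
        assert "AR(1) + CV + SD size" in names
        assert "AR(1) + CV + mean size + SD size" in names


class TestComposite:
    def test_single_member_is_identity(self):
        nz = normalize_running(raw([1, 3, 2, 5]))
        comp = composite_metric([nz])
        np.testing.assert_array_equal(comp.values, nz.values)

    def test_elementwise_sum(self):
        years = np.arange(2000, 2002)
        a = normalize_running(raw([0, 0]))
        a.values = np.array([1.0, 2.0])
        b = normalize_running(raw([0, 0]))
        b.values = np.array([0.5, -1.0])
        b.indicator_id = "AR1"
        comp = composite_metric([a, b])
        np.testing.assert_allclose(comp.values, [1.5, 1.0])

    def test_additivity_recomputation_oracle(self, rng):
        series = {i: raw(rng.normal(size=20), ind=i)
                  for i in ("AR1", "CV", "SD_SIZE")}
        members = [normalize_running(series[i]) for i in series]
        comp = composite_metric(members)
        for t in range(20):
            expected = sum(normalize_running(series[i]).values[t]
                           for i in series)
            if np.isnan(expected):
                assert np.isnan(comp.values[t])
            else:
                assert comp.values[t] == pytest.approx(expected, abs=1e-12)

    def test_missing_member_makes_composite_missing(self):
        a = normalize_running(raw([1, 2, 3, 4]))
        b = normalize_running(raw([np.nan, 1, 2, 3], ind="AR1"))
        comp = composite_metric([a, b])
        assert np.isnan(comp.values[1])    # b undefined until 2 values seen
        assert np.isfinite(comp.values[2])

    def test_year_axis_mismatch_rejected(self):
        a = normalize_running(raw([1, 2, 3]))
        b = normalize_running(raw([1, 2, 3], start=2001, ind="AR1"))
        with pytest.raises(ValueError):
            composite_metric([a, b])


def comp(values, start=2040):
    values = np.asarray(values, dtype=float)
    return CompositeMetric(("AR1",), np.arange(start, start + values.size),
                           values)


class TestDetection:
    def test_simple_threshold(self):
        cfg = DetectionConfig(assessment_window=(2040, 2043))
        got = detect_signals(comp([0, 1, 2.5, 1.9]), cfg)
        np.testing.assert_array_equal(got, [2042])

    def test_training_exceedances_disregarded(self):
        cfg = DetectionConfig(training_window=(2010, 2039),
                              assessment_window=(2040, 2090))
        metric = comp([2.5, 0.1, 2.4], start=2038)   # 2038 is training
        np.testing.assert_array_equal(detect_signals(metric, cfg), [2040])

    def test_all_below_threshold(self):
        cfg = DetectionConfig(assessment_window=(2040, 2045))
        assert detect_signals(comp([1.9, 2.0, -3]), cfg).size == 0

    def test_threshold_monotonicity(self, rng):
        for _ in range(200):
            metric = comp(rng.normal(0, 1.5, size=30))
            t1, t2 = sorted(rng.uniform(0.1, 4.0, size=2))
            lo = detect_signals(metric, DetectionConfig(
                threshold_sigma=t1, assessment_window=(2040, 2069)))
            hi = detect_signals(metric, DetectionConfig(
                threshold_sigma=t2, assessment_window=(2040, 2069)))
            assert set(hi) <= set(lo)

    def test_sqrt_k_rescaling_option(self):
        cfg = DetectionConfig(rescale_by_sqrt_k=True)
        assert cfg.threshold_for(4) == pytest.approx(4.0)
        assert DetectionConfig().threshold_for(4) == 2.0

    def test_windows_must_be_ordered(self):
        with pytest.raises(ValueError):
            DetectionConfig(training_window=(2010, 2050),
                            assessment_window=(2040, 2090))


class TestConsecutiveRule:
    def test_run_of_two(self):
        np.testing.assert_array_equal(
            consecutive_filter([2041, 2042, 2050], k=2), [2042])

    def test_no_adjacency(self):
        assert consecutive_filter([2041, 2043], k=2).size == 0

    def test_k1_is_identity(self):
        np.testing.assert_array_equal(consecutive_filter([2041, 2043], k=1),
                                      [2041, 2043])

    def test_conservatism(self, rng):
        # k=2 detections are a subset of single signals
        for _ in range(200):
            years = 2040 + np.flatnonzero(rng.random(30) < 0.3)
            assert set(consecutive_filter(years, 2)) <= set(years)

    def test_max_consecutive_run(self):
        assert max_consecutive_run([2041, 2042, 2043, 2050]) == 3
        assert max_consecutive_run([]) == 0

    def test_max_run_matches_scan_oracle(self, rng):
        for _ in range(300):
            years = np.flatnonzero(rng.random(40) < 0.4) + 2000
            best = run = 0
            prev = None
            for y in sorted(years):
                run = run + 1 if prev == y - 1 else 1
                best = max(best, run)
                prev = y
            assert max_consecutive_run(years) == best


class TestMaxStrength:
    def test_simple_max(self):
        assert max_signal_strength(comp([0.1, 2.2, 1.0]),
                                   (2040, 2042)) == pytest.approx(2.2)

    def test_window_of_one(self):
        assert max_signal_strength(comp([0.1, 2.2, 1.0]),
                                   (2041, 2041)) == pytest.approx(2.2)

    def test_all_missing_is_nan(self):
        assert np.isnan(max_signal_strength(comp([np.nan, np.nan]),
                                            (2040, 2041)))

    def test_matches_scan_oracle(self, rng):
        for _ in range(1000):
            vals = rng.normal(size=rng.integers(1, 30))
            mask = rng.random(vals.size) < 0.2
            vals[mask] = np.nan
            m = comp(vals)
            lo = 2040 + int(rng.integers(0, vals.size))
            hi = 2040 + int(rng.integers(0, vals.size))
            lo, hi = min(lo, hi), max(lo, hi)
            window = vals[lo - 2040:hi - 2040 + 1]
            finite = window[np.isfinite(window)]
            got = max_signal_strength(m, (lo, hi))
            if finite.size == 0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(finite.max())
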