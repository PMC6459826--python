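import numpy as np
import pytest

from recoverews import (SpeciesParams, build_size_grid, generate_ensemble)
from recoverews.evaluate import (ReplicateResult, analyze_ensemble,
                                 classify_replicate, default_thresholds,
                                 roc_curve, summarize_ensemble,
                                 training_length_sweep, _reclassify)
from recoverews.ewsr import CompositeMetric


def result(treatment, signals, detections=None, recovery=None,
           window=(2040, 2090), values=None, replicate=0):
    years = np.arange(2040, 2091)
    if values is None:
        values = np.zeros(years.size)
        for y in signals:
            values[y - 2040] = 3.0
    comp = CompositeMetric(("AR1", "SD_SIZE"), years, np.asarray(values))
    sig = np.asarray(sorted(signals), dtype=int)
    det = (np.asarray(sorted(detections), dtype=int) if detections is not None
           else np.empty(0, int))
    recovered = treatment != 0.0 and recovery is not None
    strength = float(np.nanmax(values)) if len(values) else float("nan")
    return ReplicateResult(treatment, replicate, "AR(1) + SD size", recovery,
                           recovered, window if recovered or treatment == 0.0
                           else None, sig, det, strength,
                           0, comp)


class TestClassification:
    def test_recovery_with_detection_is_tp(self):
        r = result(0.02, [2044], recovery=2060, window=(2040, 2060))
        assert classify_replicate(r, "single") == "TP"

    def test_control_without_detection_is_tn(self):
        assert classify_replicate(result(0.0, []), "single") == "TN"

    def test_control_with_detection_is_fp(self):
        assert classify_replicate(result(0.0, [2055]), "single") == "FP"

    def test_signal_after_recovery_point_not_counted(self):
        # composite exceeds threshold only at 2050, assessment ends 2045
        r = result(0.02, [], recovery=2045, window=(2040, 2045),
                   values=np.where(np.arange(2040, 2091) == 2050, 3.0, 0.0))
        assert classify_replicate(r, "single") == "FN"
        assert _reclassify(r, 2.0, "single") == "FN"

    def test_unrecovered_release_replicate_excluded(self):
        r = result(0.02, [], recovery=None)
        assert classify_replicate(r, "single") is None


class TestSummaries:
    def test_counting_oracle_proportions(self):
        rows = [result(0.02, [2044], recovery=2060, window=(2040, 2060),
                       replicate=0),
                result(0.02, [2050], recovery=2060, window=(2040, 2060),
                       replicate=1),
                result(0.02, [], recovery=2060, window=(2040, 2060),
                       replicate=2)]
        s = summarize_ensemble(rows, "single")
        assert s.loc[0, "proportion"] == pytest.approx(2 / 3)

    def test_lead_time_arithmetic(self):
        r = result(0.02, [2044, 2070], recovery=2090, window=(2040, 2090))
        s = summarize_ensemble([r], "single")
        assert s.loc[0, "lead_times"] == [46]

    def test_no_detections_empty_leads(self):
        rows = [result(0.02, [], recovery=2060, window=(2040, 2060))]
        s = summarize_ensemble(rows, "single")
        assert s.loc[0, "proportion"] == 0.0
        assert s.loc[0, "lead_times"] == []

    def test_se_formula(self):
        rows = [result(0.0, [], values=np.full(51, v), replicate=i)
                for i, v in enumerate([1.0, 2.0, 3.0])]
        s = summarize_ensemble(rows, "single")
        assert s.loc[0, "mean_max_strength"] == pytest.approx(2.0)
        assert s.loc[0, "se_max_strength"] == pytest.approx(1.0 / np.sqrt(3))


@pytest.fixture(scope="module")
def toy_ensemble():
    grid = build_size_grid()
    return generate_ensemble(SpeciesParams(), treatments=(0.0, 0.05, 0.10),
                             n_reps=10, base_seed=555, grid=grid,
                             burn_in="fast")


@pytest.fixture(scope="module")
def toy_results(toy_ensemble):
    return analyze_ensemble(toy_ensemble, metrics=[("AR1", "SD_SIZE")])


class TestROC:
    def test_extreme_thresholds(self, toy_results):
        highest = max(np.nanmax(r.composite.values) for r in toy_results)
        lowest = min(np.nanmin(r.composite.values) for r in toy_results)
        curve = roc_curve(toy_results, "AR(1) + SD size", "single",
                          thresholds=[lowest - 1.0, highest + 1.0])
        assert (curve.fpr[0], curve.tpr[0]) == (1.0, 1.0)
        assert (curve.fpr[1], curve.tpr[1]) == (0.0, 0.0)

    def test_monotone_in_threshold(self, toy_results):
        for rule in ("single", "consecutive"):
            curve = roc_curve(toy_results, "AR(1) + SD size", rule)
            assert np.all(np.diff(curve.fpr) <= 1e-12)
            assert np.all(np.diff(curve.tpr) <= 1e-12)

    def test_brute_force_reclassification_oracle(self, toy_results):
        curve = roc_curve(toy_results, "AR(1) + SD size", "single",
                          thresholds=[0.5, 2.0, 3.5])
        for i, th in enumerate([0.5, 2.0, 3.5]):
            tp = fn = fp = tn = 0
            for r in toy_results:
                if r.assessment_window is None:
                    continue
                lo, hi = r.assessment_window
                m = (r.composite.years >= lo) & (r.composite.years <= hi)
                vals = r.composite.values[m]
                hit = np.any(vals[np.isfinite(vals)] > th)
                if r.treatment == 0.0:
                    fp, tn = fp + hit, tn + (not hit)
                else:
                    tp, fn = tp + hit, fn + (not hit)
            assert curve.tpr[i] == pytest.approx(tp / (tp + fn))
            assert curve.fpr[i] == pytest.approx(fp / (fp + tn))

    def test_grid_spans_and_contains_operating_point(self):
        th = default_thresholds()
        assert th.min() == pytest.approx(0.01)
        assert th.max() == pytest.approx(6.0)
        assert 2.0 in th

    def test_requires_control_and_recovery(self, toy_results):
        only_rec = [r for r in toy_results if r.treatment > 0]
        with pytest.raises(ValueError):
            roc_curve(only_rec, "AR(1) + SD size")

    def test_rule_dominance_at_all_thresholds(self, toy_results):
        single = roc_curve(toy_results, "AR(1) + SD size", "single")
        consec = roc_curve(toy_results, "AR(1) + SD size", "consecutive")
        assert np.all(consec.tpr <= single.tpr + 1e-12)
        assert np.all(consec.fpr <= single.fpr + 1e-12)


class TestTrainingSweep:
    def test_sweep_shape_and_consistency(self, toy_ensemble, toy_results):
        sweep = training_length_sweep(toy_ensemble, "AR(1) + SD size",
                                      lengths=[2, 10, 30])
        assert set(sweep["length"]) == {2, 10, 30}
        assert len(sweep) == 6                      # one row per (L, rule)
        # L=30 reproduces the default-analysis proportions exactly
        for rule in ("single", "consecutive"):
            out = [classify_replicate(r, rule) for r in toy_results]
            tp, fn = out.count("TP"), out.count("FN")
            fp, tn = out.count("FP"), out.count("TN")
            row = sweep[(sweep.length == 30) & (sweep.rule == rule)].iloc[0]
            assert row.tp_proportion == pytest.approx(tp / (tp + fn))
            assert row.fp_proportion == pytest.approx(fp / (fp + tn))

    def test_rule_dominance_at_each_length(self, toy_ensemble):
        sweep = training_length_sweep(toy_ensemble, "AR(1) + SD size",
                                      lengths=[5, 20])
        for L in (5, 20):
            s = sweep[(sweep.length == L) & (sweep.rule == "single")].iloc[0]
            c = sweep[(sweep.length == L)
                      & (sweep.rule == "consecutive")].iloc[0]
            assert c.tp_proportion <= s.tp_proportion + 1e-12
            assert c.fp_proportion <= s.fp_proportion + 1e-12

    def test_too_short_length_rejected(self, toy_ensemble):
        with pytest.raises(ValueError):
            training_length_sweep(toy_ensemble, "AR(1) + SD size",
                                  lengths=[1])
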