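"""Component-level matching, metric arithmetic, pooling and stratification."""

import numpy as np
import pytest

from carieseg import (
    LesionRecord,
    SeverityLabel,
    ValidationError,
    component_metrics,
    f1_score,
    match_components,
    pool_cross_validation,
    severity_sensitivity,
)
from carieseg.evaluate import MatchResult, NoDetectionsNoTruth


def exhaustive_match(pred_sets, truth_sets, theta):
    """Independent all-pairs pixel-intersection oracle."""
    qualifies = [[len(p & t) / len(t) >= theta for t in truth_sets] for p in pred_sets]
    tp = sum(any(qualifies[p][t] for p in range(len(pred_sets)))
             for t in range(len(truth_sets)))
    fn = len(truth_sets) - tp
    fp = sum(not any(row) for row in qualifies)
    return tp, fp, fn


def _lesion(pixels, severity=SeverityLabel.MODERATE, lid="L"):
    return LesionRecord(lesion_id=lid, pixel_set=frozenset(pixels),
                        penetration=0.5, severity=severity)


class TestMatchComponents:
    def test_identical_blob_is_hit(self):
        pix = {(1, 1), (1, 2)}
        m = match_components([pix], [_lesion(pix)], theta=0.1)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)
        assert m.pairings == [(0, 0, 1.0)]

    def test_five_percent_overlap_misses_at_theta_ten(self):
        lesion = _lesion({(0, c) for c in range(20)})
        blob = {(0, 0)}  # covers 5% of the lesion
        m = match_components([blob], [lesion], theta=0.1)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_many_to_many(self):
        a = _lesion({(0, 0), (0, 1)}, lid="a")
        b = _lesion({(2, 0), (2, 1)}, lid="b")
        blob = {(0, 0), (0, 1), (1, 0), (2, 0), (2, 1)}
        m = match_components([blob], [a, b], theta=0.5)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_theta_monotonicity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            grid = rng.random((15, 15))
            pred = [frozenset(map(tuple, np.argwhere(grid > 0.6)))]
            truth = [_lesion(set(map(tuple, np.argwhere(grid < 0.5))))]
            tps = [match_components(pred, truth, theta=t).tp
                   for t in (0.05, 0.2, 0.5, 0.9)]
            assert tps == sorted(tps, reverse=True)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50)        :
            h = w = 20
            n_pred = int(rng.integers(0, 4))
            n_truth = int(rng.integers(1, 4))
            preds = [frozenset((int(r), int(c)) for r, c in
                               rng.integers(0, h, (int(rng.integers(1, 30)), 2)))
                     for _ in range(n_pred)]
            truths = [_lesion(set((int(r), int(c)) for r, c in
                                  rng.integers(0, h, (int(rng.integers(1, 30)), 2))),
                              lid=str(i)) for i in range(n_truth)]
            m = match_components(preds, truths, theta=0.1)
            assert (m.tp, m.fp, m.fn) == exhaustive_match(
                preds, [t.pixel_set for t in truths], 0.1)

    def test_count_conservation(self):
        rng = np.random.default_rng(2)
        preds = [frozenset({(int(r), int(c))}) for r, c in rng.integers(0, 10, (5, 2))]
        truths = [_lesion({(int(r), int(c))}, lid=str(i))
                  for i, (r, c) in enumerate(rng.integers(0, 10, (7, 2)))]
        m = match_components(preds, truths, theta=0.5)
        assert m.tp + m.fn == len(truths)

    def test_theta_out_of_range(self):
        with pytest.raises(ValidationError):
            match_components([], [], theta=0.0)


class TestMetrics:
    def test_arithmetic(self):
        rep = component_metrics(MatchResult(theta=0.1, tp=2, fp=1, fn=2))
        assert rep.precision == pytest.approx(66.6667, abs=1e-3)
        assert rep.recall == pytest.approx(50.0)

    def test_zero_tp(self):
        rep = component_metrics(MatchResult(theta=0.1, tp=0, fp=3, fn=2))
        assert rep.precision == 0.0 and rep.recall == 0.0
        assert rep.f1 == 0.0 and not rep.f1_defined

    def test_perfect_detection(self):
        rep = component_metrics(MatchResult(theta=0.1, tp=5, fp=0, fn=0))
        assert rep.precision == rep.recall == rep.f1 == 100.0

    def test_no_detections_no_truth_signal(self):
        with pytest.raises(NoDetectionsNoTruth):
            component_metrics(MatchResult(theta=0.1, tp=0, fp=0, fn=0))

    def test_absent_metric_reported_as_none(self):
        rep = component_metrics(MatchResult(theta=0.1, tp=0, fp=0, fn=3))
        assert rep.precision is None and rep.recall == 0.0


class TestF1Score:
    def test_harmonic_mean_examples(self):
        assert f1_score(100.0, 100.0) == pytest.approx(100.0)
        assert f1_score(40.0, 40.0) == pytest.approx(40.0)  # fixed point
        assert f1_score(0.0, 50.0) == pytest.approx(0.0)

    def test_clinical_worked_example(self):
        # a precision of 63.29% and recall of 65.02% give an F1 of 64.14%
        # after 2-decimal rounding
        assert round(f1_score(63.29, 65.02), 2) == 64.14

    def test_both_zero_degenerate(self):
        assert f1_score(0.0, 0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            f1_score(120.0, 50.0)


class TestPooling:
    def test_pooled_counts(self):
        folds = [MatchResult(theta=0.1, tp=1, fp=1, fn=0),
                 MatchResult(theta=0.1, tp=1, fp=0, fn=1)]
        rep = pool_cross_validation(folds)
        assert rep.precision == pytest.approx(66.6667, abs=1e-3)
        assert rep.recall == pytest.approx(66.6667, abs=1e-3)

    def test_single_fold_is_identity(self):
        fold = MatchResult(theta=0.1, tp=3, fp=2, fn=1)
        pooled = pool_cross_validation([fold])
        direct = component_metrics(fold)
        assert pooled.precision == direct.precision
        assert pooled.recall == direct.recall

    def test_pooling_differs_from_mean_of_folds(self):
        # asymmetric fold sizes: pooled recall weights lesions equally,
        # the mean of per-fold recalls does not
        folds = [MatchResult(theta=0.1, tp=9, fp=0, fn=1),
                 MatchResult(theta=0.1, tp=0, fp=0, fn=1)]
        pooled = pool_cross_validation(folds).recall
        mean_of_folds = np.mean([90.0, 0.0])
        assert pooled == pytest.approx(9 / 11 * 100)
        assert pooled != pytest.approx(mean_of_folds)

    def test_mixed_theta_rejected(self):
        with pytest.raises(ValidationError):
            pool_cross_validation([MatchResult(theta=0.1, tp=1, fp=0, fn=0),
                                   MatchResult(theta=0.2, tp=1, fp=0, fn=0)])


class TestSeveritySensitivity:
    def test_single_pixel_overlap_counts(self):
        lesion = _lesion({(0, c) for c in range(30)}, SeverityLabel.INITIAL)
        out = severity_sensitivity({"r": [frozenset({(0, 0)})]}, {"r": [lesion]})
        assert out["initial"] == 100.0 and out["overall"] == 100.0

    def test_no_detections_zero_everywhere(self):
        truth = {"r": [_lesion({(0, 0)}, SeverityLabel.INITIAL, "a"),
                       _lesion({(5, 5)}, SeverityLabel.MODERATE, "b")]}
        out = severity_sensitivity({"r": []}, truth)
        assert out["initial"] == 0.0 and out["moderate"] == 0.0
        assert out["extensive"] is None  # empty class is absent, not zero

    def test_class_counts(self):
        lesions = ([_lesion({(0, i)}, SeverityLabel.INITIAL, f"i{i}") for i in range(4)]
                   + [_lesion({(5, i)}, SeverityLabel.MODERATE, f"m{i}") for i in range(3)])
        dets = [frozenset({(0, 0)}), frozenset({(0, 1)}),
                frozenset({(5, 0)}), frozenset({(5, 1)}), frozenset({(5, 2)})]
        out = severity_sensitivity({"r": dets}, {"r": lesions})
        assert out["initial"] == pytest.approx(50.0)
        assert out["moderate"] == pytest.approx(100.0)
        assert out["overall"] == pytest.approx(5 / 7 * 100)
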