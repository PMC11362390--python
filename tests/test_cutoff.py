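"""Youden-index cut-off estimation, classification, and the log curve fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from lsci.cutoff import (
    LogCurveRegression,
    YoudenCutoffClassifier,
    classify,
    log_curve_fit,
    optimal_cutoff,
    youden_index,
)
from lsci.errors import DomainError, UsageError


def brute_force_cutoff(pos, neg, direction):
    """Independent exhaustive scan over every candidate threshold."""
    values = sorted(set(pos) | set(neg))
    cands = [values[0] - 1.0]
    cands += [(a + b) / 2.0 for a, b in zip(values, values[1:])]
    cands += [values[-1] + 1.0]
    best = None
    for t in cands:
        if direction == "below_positive":
            sens = sum(v < t for v in pos) / len(pos)
            spec = sum(v >= t for v in neg) / len(neg)
        else:
            sens = sum(v > t for v in pos) / len(pos)
            spec = sum(v <= t for v in neg) / len(neg)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    return best


class TestYoudenIndex:
    @pytest.mark.parametrize(
        "sens, spec, j",
        [(0.94, 0.87, 0.81), (0.97, 1.00, 0.97), (1.0, 1.0, 1.0)],
    )
    def test_reported_operating_points(self, sens, spec, j):
        assert youden_index(sens, spec) == pytest.approx(j)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            youden_index(1.2, 0.5)
        with pytest.raises(DomainError):
            youden_index(0.5, -0.1)


class TestOptimalCutoff:
    def test_perfect_separation(self):
        res = optimal_cutoff(
            (np.array([40, 50, 60, 80, 90, 100.0]),
             np.array(["ischemic"] * 3 + ["well"] * 3)),
            "below_positive",
        )
        assert res.threshold == pytest.approx(70.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.youden_j == pytest.approx(1.0)

    def test_tie_broken_to_smallest_threshold(self):
        # J = 2/3 at both 65 and 85; the smaller cut-off must win
        res = optimal_cutoff(
            (np.array([50, 60, 80, 70, 90, 100.0]),
             np.array(["ischemic"] * 3 + ["well"] * 3)),
            "below_positive",
        )
        assert res.threshold == pytest.approx(65.0)
        assert res.youden_j == pytest.approx(2.0 / 3.0)

    def test_above_positive_constant_classes(self):
        res = optimal_cutoff(
            (np.array([2.0, 2.0, 2.0, 8.0, 8.0, 8.0]),
             np.array(["well"] * 3 + ["ischemic"] * 3)),
            "above_positive",
        )
        assert res.threshold == pytest.approx(5.0)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(UsageError):
            optimal_cutoff((np.array([1.0, 2.0]), np.array(["well", "well"])))

    def test_roc_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        values = np.r_[rng.normal(50, 15, 40), rng.normal(90, 15, 40)]
        labels = np.array(["ischemic"] * 40 + ["well"] * 40)
        res = optimal_cutoff((values, labels), "below_positive")
        sens = [p[1] for p in res.roc]
        spec = [p[2] for p in res.roc]
        assert np.all(np.diff(sens) >= 0)
        assert np.all(np.diff(spec) <= 0)

    @given(
        pos=st.lists(st.integers(0, 40), min_size=1, max_size=15),
        neg=st.lists(st.integers(0, 40), min_size=1, max_size=15),
        direction=st.sampled_from(["below_positive", "above_positive"]),
    )
    @settings(max_examples=250, deadline=None, derandomize=True)
    def test_matches_exhaustive_scan(self, pos, neg, direction):
        values = np.array(pos + neg, dtype=float)
        if len(np.unique(values)) < 2:
            return
        labels = np.array(["ischemic"] * len(pos) + ["well"] * len(neg))
        res = optimal_cutoff((values, labels), direction)
        j, t, sens, spec = brute_force_cutoff(pos, neg, direction)
        assert res.youden_j == pytest.approx(j)
        assert res.threshold == pytest.approx(t)
        assert res.sensitivity == pytest.approx(sens)
        assert res.specificity == pytest.approx(spec)


class TestClassify:
    def test_below_positive_rule(self):
        assert classify(68.0, 69.0, "below_positive") == "ischemic"
        assert classify(69.0, 69.0, "below_positive") == "well"  # boundary -> well

    def test_above_positive_rule(self):
        assert classify(4.0, 3.8, "above_positive") == "ischemic"
        assert classify(3.8, 3.8, "above_positive") == "well"

    def test_estimator_predict_agrees_with_classify(self):
        X = np.array([40.0, 60.0, 80.0, 95.0])
        y = np.array(["ischemic", "ischemic", "well", "well"])
        est = YoudenCutoffClassifier().fit(X, y)
        assert np.array_equal(est.predict(X), classify(X, est.threshold_))

    def test_estimator_is_cloneable(self):
        est = YoudenCutoffClassifier(direction="above_positive")
        assert clone(est).get_params()["direction"] == "above_positive"


class TestLogCurveFit:
    def test_noiseless_log_identity(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        fit = log_curve_fit(x, np.log(x))
        assert fit.b0 == pytest.approx(0.0, abs=1e-12)
        assert fit.b1 == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_three_points(self):
        x = np.array([1.0, np.e, np.e**2])
        fit = log_curve_fit(x, [2.0, 3.0, 4.0])
        assert fit.b0 == pytest.approx(2.0)
        assert fit.b1 == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y_flagged_undefined(self):
        with pytest.warns(UserWarning):
            fit = log_curve_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert fit.b1 == pytest.approx(0.0, abs=1e-12)
        assert not fit.r2_defined

    def test_nonpositive_x_rejected(self):
        with pytest.raises(DomainError):
            log_curve_fit([1.0, 0.0, 2.0], [1.0, 2.0, 3.0])

    def test_r_squared_in_unit_interval_with_noise(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1.0, 100.0, 60)
        y = 2.0 - 3.0 * np.log(x) + rng.normal(0, 2.0, 60)
        fit = log_curve_fit(x, y)
        assert 0.0 <= fit.r_squared <= 1.0
        est = LogCurveRegression().fit(x, y)
        assert est.score(x, y) == pytest.approx(fit.r_squared)
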