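"""Youden-index cut-offs, tissue classification, and the log LSPU-lactate fit.

The threshold estimator scans every candidate cut-off (midpoints between
consecutive sorted distinct values, plus sentinels below the minimum and
above the maximum) and keeps the one with the highest Youden index
``J = sensitivity + specificity - 1``; ties go to the smallest threshold.

Two diagnostic conventions are supported:

``below_positive``
    LSPU convention — tissue with a value *below* the cut-off is called
    ischemic (positive); sensitivity = P(ischemic value < t),
    specificity = P(well value >= t).
``above_positive``
    lactate convention — a value *above* the cut-off marks ischemia; the
    inequalities mirror.

Both the classifier and the logarithmic curve fit are scikit-learn
estimators, so they compose with pipelines and model selection; the
module-level functions are thin wrappers returning plain result records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DomainError, UsageError

__all__ = [
    "LabeledValue",
    "CutoffResult",
    "LogFitResult",
    "youden_index",
    "optimal_cutoff",
    "classify",
    "log_curve_fit",
    "YoudenCutoffClassifier",
    "LogCurveRegression",
]

BELOW_POSITIVE = "below_positive"
ABOVE_POSITIVE = "above_positive"

LABEL_ISCHEMIC = "ischemic"
LABEL_WELL = "well"


@dataclass
class LabeledValue:
    """A measurement with its anatomical ground-truth class."""

    value: float
    label: str  # "ischemic" or "well"
    loop_id: str = ""
    timepoint: str = ""


@dataclass
class CutoffResult:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    direction: str
    roc: list  # (threshold, sensitivity, specificity) per candidate, ascending


@dataclass
class LogFitResult:
    b0: float  # intercept
    b1: float  # slope on ln(x)
    r_squared: float
    r2_defined: bool = True

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.b0 + self.b1 * np.log(x)


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity - 1 (both arguments in [0, 1])."""
    if not (0.0 <= sensitivity <= 1.0) or not (0.0 <= specificity <= 1.0):
        raise DomainError("sensitivity and specificity must be in [0, 1]")
    return sensitivity + specificity - 1.0


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))


class YoudenCutoffClassifier(ClassifierMixin, BaseEstimator):
    """Single-threshold diagnostic classifier fitted by Youden-index scan.

    Parameters
    ----------
    direction : str
        ``"below_positive"`` (LSPU) or ``"above_positive"`` (lactate).
    positive_label, negative_label : str
        Class names for the positive (diseased/ischemic) and negative
        (healthy/well-perfused) classes.

    Attributes
    ----------
    threshold_ : float
        The Youden-optimal cut-off (ties broken toward the smallest).
    sensitivity_, specificity_, youden_j_ : float
        Operating point of the selected cut-off.
    roc_ : list of (threshold, sensitivity, specificity)
        Operating points of every candidate, thresholds ascending.
    classes_ : ndarray
        The two class labels seen during fit.
    """

    def __init__(
        self,
        direction: str = BELOW_POSITIVE,
        positive_label: str = LABEL_ISCHEMIC,
        negative_label: str = LABEL_WELL,
    ):
        self.direction = direction
        self.positive_label = positive_label
        self.negative_label = negative_label

    def fit(self, X, y):
        if self.direction not in (BELOW_POSITIVE, ABOVE_POSITIVE):
            raise DomainError(f"unknown direction {self.direction!r}")
        values = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y)
        if values.shape[0] != y.shape[0]:
            raise UsageError("X and y lengths differ")
        if not np.all(np.isfinite(values)):
            raise DomainError("values must be finite")
        pos = values[y == self.positive_label]
        neg = values[y == self.negative_label]
        if len(pos) == 0 or len(neg) == 0:
            raise UsageError("both classes must be present")
        if len(np.unique(values)) < 2:
            raise UsageError("need at least 2 distinct values")

        thr = _candidate_thresholds(values)
        pos_sorted = np.sort(pos)
        neg_sorted = np.sort(neg)
        if self.direction == BELOW_POSITIVE:
            # sensitivity: fraction of positives strictly below t
            sens = np.searchsorted(pos_sorted, thr, side="left") / len(pos)
            # specificity: fraction of negatives at or above t
            spec = 1.0 - np.searchsorted(neg_sorted, thr, side="left") / len(neg)
        else:
            sens = 1.0 - np.searchsorted(pos_sorted, thr, side="right") / len(pos)
            spec = np.searchsorted(neg_sorted, thr, side="right") / len(neg)

        j = sens + spec - 1.0
        # first (= smallest threshold) among ties, robust to 1-ulp float noise
        best = int(np.argmax(j >= j.max() - 1e-12))
        self.threshold_ = float(thr[best])
        self.sensitivity_ = float(sens[best])
        self.specificity_ = float(spec[best])
        self.youden_j_ = float(j[best])
        self.roc_ = list(zip(thr.tolist(), sens.tolist(), spec.tolist()))
        self.classes_ = np.array(sorted([self.positive_label, self.negative_label]))
        return self

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        values = np.asarray(X, dtype=float).reshape(-1)
        return classify(
            values,
            self.threshold_,
            self.direction,
            positive_label=self.positive_label,
            negative_label=self.negative_label,
        )

    def result(self) -> CutoffResult:
        check_is_fitted(self, "threshold_")
        return CutoffResult(
            threshold=self.threshold_,
            sensitivity=self.sensitivity_,
            specificity=self.specificity_,
            youden_j=self.youden_j_,
            direction=self.direction,
            roc=self.roc_,
        )


def optimal_cutoff(data, direction: str = BELOW_POSITIVE) -> CutoffResult:
    """Youden-optimal cut-off from labelled values.

    ``data`` is either a sequence of :class:`LabeledValue` or a
    ``(values, labels)`` pair.
    """
    if isinstance(data, tuple) and len(data) == 2:
        values, labels = data
    else:
        data = list(data)
        values = [d.value for d in data]
        labels = [d.label for d in data]
    est = YoudenCutoffClassifier(direction=direction)
    est.fit(np.asarray(values, dtype=float), np.asarray(labels))
    return est.result()


def classify(
    values,
    cutoff: float,
    direction: str = BELOW_POSITIVE,
    positive_label: str = LABEL_ISCHEMIC,
    negative_label: str = LABEL_WELL,
):
    """Apply a cut-off: strict inequality marks the positive class.

    ``below_positive``: value < cutoff -> ischemic, value >= cutoff -> well.
    ``above_positive``: value > cutoff -> ischemic, value <= cutoff -> well.
    A value exactly at the cut-off is therefore always classified well.
    """
    values = np.asarray(values, dtype=float)
    if direction == BELOW_POSITIVE:
        is_pos = values < cutoff
    elif direction == ABOVE_POSITIVE:
        is_pos = values > cutoff
    else:
        raise DomainError(f"unknown direction {direction!r}")
    out = np.where(is_pos, positive_label, negative_label)
    return out if values.ndim else out[()]


class LogCurveRegression(RegressorMixin, BaseEstimator):
    """Ordinary least squares of y on ln(x) with intercept.

    Attributes (after fit): ``intercept_`` (b0), ``slope_`` (b1),
    ``r_squared_`` and ``r2_defined_`` (False when y has zero variance).
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if len(x) != len(y):
            raise UsageError("x and y lengths differ")
        if len(x) < 3:
            raise UsageError("need at least 3 points")
        if np.any(x <= 0) or not np.all(np.isfinite(x)):
            raise DomainError("x values must be finite and > 0")
        lx = np.log(x)
        design = np.column_stack([np.ones_like(lx), lx])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        self.intercept_, self.slope_ = float(coef[0]), float(coef[1])
        resid = y - design @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0.0:
            warnings.warn("y has zero variance; R^2 undefined")
            self.r_squared_ = float("nan")
            self.r2_defined_ = False
        else:
            self.r_squared_ = 1.0 - ss_res / ss_tot
            self.r2_defined_ = True
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        x = np.asarray(X, dtype=float).reshape(-1)
        if np.any(x <= 0):
            raise DomainError("x values must be > 0")
        return self.intercept_ + self.slope_ * np.log(x)


def log_curve_fit(x, y) -> LogFitResult:
    """Logarithmic curve estimation: ``y = b0 + b1 ln(x)`` by OLS."""
    est = LogCurveRegression().fit(x, y)
    return LogFitResult(
        b0=est.intercept_,
        b1=est.slope_,
        r_squared=est.r_squared_,
        r2_defined=est.r2_defined_,
    )
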