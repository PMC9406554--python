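"""Threshold classification of 1-D biomarker values.

Two cut-point methods on a labeled biomarker (failure = positive class):

* **Max threshold** — exhaustive search over candidate cut points (midpoints
  of consecutive sorted unique values, plus the unbounded extremes) for the
  accuracy-maximising rule; ties resolved to the midpoint of the widest
  optimal interval, for stability under perturbation.
* **SVM threshold** — a linear soft-margin support vector classifier on the
  standardised 1-D feature (C = 1 by default), its decision boundary mapped
  back to the original scale.

Robustness is assessed with seeded, stratified k-fold cross-validation,
re-fitting the threshold on each training split and replicating the shuffled
procedure many times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

PREDICT_ABOVE = "predict_failure_if_above"
PREDICT_BELOW = "predict_failure_if_below"

#: Direction convention by biomarker kind: the q2 ratio rises with
#: resistance, the androgen/PSA ratio falls.
DIRECTION_BY_KIND = {
    "q2_ratio": PREDICT_ABOVE,
    "ap_ratio": PREDICT_BELOW,
    "ap_ratio_final": PREDICT_BELOW,
    "ap_ratio_early": PREDICT_BELOW,
}


@dataclass(frozen=True)
class ThresholdRule:
    threshold: float
    direction: str               # PREDICT_ABOVE | PREDICT_BELOW
    method: str                  # "max" | "svm"
    kind: str = ""

    def predict(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.direction == PREDICT_ABOVE:
            return values > self.threshold
        return values < self.threshold


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def evaluate(rule: ThresholdRule, values, labels) -> ConfusionSummary:
    """Confusion counts and accuracy/sensitivity/specificity of a rule.

    ``labels`` are truthy for treatment failure (the positive class).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = rule.predict(values)
    return ConfusionSummary(
        tp=int(np.sum(pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        tn=int(np.sum(~pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
    )


def _accuracy_above(threshold: float, values: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean((values > threshold) == labels))


def max_threshold(values, labels, direction: str, kind: str = "") -> tuple[ThresholdRule, ConfusionSummary]:
    """Accuracy-maximising cut point by exhaustive candidate search.

    Accuracy as a function of the threshold is piecewise constant with
    breakpoints at the observed values, so scanning the midpoints of
    consecutive sorted unique values (plus the two unbounded extremes) finds
    the global optimum.  Among optimal intervals the widest finite one wins
    and its midpoint is returned; if only an unbounded interval is optimal
    the rule degenerates to +/-inf (everything one class).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not np.all(np.isfinite(values)):
        raise ValueError("biomarker values must be finite")
    if direction not in (PREDICT_ABOVE, PREDICT_BELOW):
        raise ValueError(f"unknown direction {direction!r}")
    if labels.all() or not labels.any():
        import warnings

        warnings.warn("only one outcome class present; the Max threshold "
                      "degenerates to an unbounded rule", stacklevel=2)

    # work in "predict above" orientation: flip the sign for "below"
    v = values if direction == PREDICT_ABOVE else -values
    uniq = np.unique(v)
    # candidate intervals between consecutive unique values, plus extremes
    edges = np.concatenate(([-np.inf], uniq, [np.inf]))
    best_acc, best_lo, best_hi = -1.0, -np.inf, np.inf
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(lo) and np.isinf(hi):
            continue
        probe = (hi - 1.0 if np.isinf(lo)
                 else lo + 1.0 if np.isinf(hi)
                 else 0.5 * (lo + hi))
        acc = _accuracy_above(probe, v, labels)
        width = hi - lo
        best_width = best_hi - best_lo
        if acc > best_acc + 1e-12 or (
            abs(acc - best_acc) <= 1e-12
            and np.isfinite(width) and (not np.isfinite(best_width) or width > best_width)
        ):
            best_acc, best_lo, best_hi = acc, lo, hi

    if np.isfinite(best_lo) and np.isfinite(best_hi):
        thr = 0.5 * (best_lo + best_hi)
    elif np.isinf(best_lo):
        thr = -np.inf   # everything predicted failure
    else:
        thr = np.inf    # nothing predicted failure
    if direction == PREDICT_BELOW:
        thr = -thr
    rule = ThresholdRule(float(thr), direction, "max", kind)
    return rule, evaluate(rule, values, labels)


def svm_threshold(
    values, labels, direction: str, kind: str = "", C: float = 1.0
) -> tuple[ThresholdRule, ConfusionSummary]:
    """Linear soft-margin SVM decision boundary on the 1-D biomarker.

    The feature is standardised internally and the boundary (-intercept /
    coefficient) mapped back to the original scale.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present for the SVM threshold")
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: all biomarker values identical")

    mean, std = values.mean(), values.std()
    z = ((values - mean) / std).reshape(-1, 1)
    clf = SVC(kernel="linear", C=C, tol=1e-8)
    clf.fit(z, labels.astype(int))
    w = float(clf.coef_[0][0])
    b = float(clf.intercept_[0])
    z_star = -b / w
    thr = mean + std * z_star
    rule = ThresholdRule(float(thr), direction, "svm", kind)
    return rule, evaluate(rule, values, labels)


@dataclass
class CVReport:
    method: str
    k: int
    replicates: int
    train_accuracies: np.ndarray   # shape (replicates, k)
    holdout_accuracies: np.ndarray
    seed: int

    @property
    def mean_train_accuracy(self) -> float:
        return float(self.train_accuracies.mean())

    @property
    def mean_holdout_accuracy(self) -> float:
        return float(self.holdout_accuracies.mean())

    def to_dict(self) -> dict:
        return {
            "method": self.method, "k": self.k, "replicates": self.replicates,
            "seed": self.seed,
            "mean_train_accuracy": self.mean_train_accuracy,
            "mean_holdout_accuracy": self.mean_holdout_accuracy,
        }


def cross_validate(
    values, labels, direction: str, method: str = "max",
    k: int = 5, replicates: int = 100, seed: int = 0, C: float = 1.0,
) -> CVReport:
    """Stratified k-fold CV of a threshold method, replicated with reshuffles.

    Each replicate shuffles, splits stratified by label, refits the
    threshold on the training folds and scores both splits; the report
    carries the full fold-level accuracy arrays.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_min = min(labels.sum(), (~labels).sum())
    if n_min < k:
        raise ValueError(
            f"stratified {k}-fold CV needs >= {k} patients of each class "
            f"(minority class has {n_min})"
        )
    fitter = max_threshold if method == "max" else svm_threshold

    train = np.empty((replicates, k))
    hold = np.empty((replicates, k))
    rng = np.random.default_rng(seed)
    for r in range(replicates):
        splitter = StratifiedKFold(
            n_splits=k, shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        for j, (tr, te) in enumerate(splitter.split(values.reshape(-1, 1), labels)):
            if method == "svm":
                rule, conf = fitter(values[tr], labels[tr], direction, C=C)
            else:
                rule, conf = fitter(values[tr], labels[tr], direction)
            train[r, j] = conf.accuracy
            hold[r, j] = evaluate(rule, values[te], labels[te]).accuracy
    return CVReport(method, k, replicates, train, hold, seed)


@dataclass
class ThresholdResults:
    """Fitted decision rule with its training confusion summary."""

    rule: ThresholdRule
    confusion: ConfusionSummary
    values: np.ndarray
    labels: np.ndarray

    def cross_validate(self, k: int = 5, replicates: int = 100, seed: int = 0) -> CVReport:
        return cross_validate(self.values, self.labels, self.rule.direction,
                              self.rule.method, k, replicates, seed)

    def summary(self) -> str:
        c = self.confusion
        return "\n".join([
            f"Threshold rule ({self.rule.method}, {self.rule.kind or 'biomarker'})",
            f"  threshold: {self.rule.threshold:.4g}  "
            f"({'failure if above' if self.rule.direction == PREDICT_ABOVE else 'failure if below'})",
            f"  confusion: TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}  (n={c.total})",
            f"  accuracy:    {100 * c.accuracy:.1f}%",
            f"  sensitivity: {100 * c.sensitivity:.1f}%",
            f"  specificity: {100 * c.specificity:.1f}%",
        ])

    def plot(self, ax=None):
        """Scatter of biomarker values by outcome with the threshold line.

        Display convention: values above 5 are drawn at 5."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        shown = np.minimum(self.values, 5.0)
        jitter = np.linspace(0, 1, len(shown))
        ax.scatter(jitter[self.labels], shown[self.labels],
                   color="tab:red", label="failure")
        ax.scatter(jitter[~self.labels], shown[~self.labels],
                   color="tab:green", label="success")
        if np.isfinite(self.rule.threshold):
            ax.axhline(min(self.rule.threshold, 5.0), ls="--", color="k",
                       label=f"{self.rule.method} threshold")
        ax.set_ylabel(self.rule.kind or "biomarker value")
        ax.legend()
        return ax


class ThresholdModel:
    """Model object for 1-D biomarker threshold classification.

    ``ThresholdModel(values, labels, kind="q2_ratio").fit(method="max")``
    returns :class:`ThresholdResults`.  Direction is inferred from the
    biomarker kind unless given explicitly.
    """

    def __init__(self, values, labels, kind: str = "", direction: Optional[str] = None):
        self.values = np.asarray(values, dtype=float)
        self.labels = np.asarray(labels, dtype=bool)
        if direction is None:
            if kind not in DIRECTION_BY_KIND:
                raise ValueError(f"cannot infer direction for kind {kind!r}")
            direction = DIRECTION_BY_KIND[kind]
        self.direction = direction
        self.kind = kind

    def fit(self, method: str = "max", C: float = 1.0) -> ThresholdResults:
        if method == "max":
            rule, conf = max_threshold(self.values, self.labels, self.direction, self.kind)
        elif method == "svm":
            rule, conf = svm_threshold(self.values, self.labels, self.direction, self.kind, C=C)
        else:
            raise ValueError(f"unknown method {method!r}")
        return ThresholdResults(rule, conf, self.values, self.labels)
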