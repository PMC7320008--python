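"""Composite connectivity biomarkers and ROC validation.

A composite score is built from the correlation values of selected ROI
pairs — either their plain sum (so an operating threshold lives on the
same scale as a sum of correlations) or the linear predictor of a
logistic regression of group on the pair correlations, fit on the test
cohort only.  The empirical ROC curve, its AUC (trapezoidal rule, equal
to the Mann-Whitney U statistic divided by n+ * n-), a DeLong confidence
interval, Youden-optimal threshold selection on the test cohort, and
frozen-threshold evaluation on an independent validation cohort complete
the workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RocResult",
    "CompositeModel",
    "composite_score",
    "roc_curve",
    "select_threshold",
    "external_validate",
    "delong_ci",
]

POSITIVE_CLASS = "arthritic"


@dataclass
class CompositeModel:
    """Frozen composite-biomarker definition (pairs, mode, coefficients)."""

    pairs: list[str]
    mode: str  # "sum" or "logistic"
    intercept: float = 0.0
    coefficients: np.ndarray | None = None
    ridge_fallback: bool = False
    fit_animal_ids: list[str] = field(default_factory=list)

    def score(self, dataset: pd.DataFrame) -> pd.Series:
        x = dataset[self.pairs].to_numpy(dtype=float)
        if self.mode == "sum":
            s = x.sum(axis=1)
        else:
            s = self.intercept + x @ self.coefficients
        return pd.Series(s, index=dataset.index, name="score")


@dataclass
class RocResult:
    """Empirical ROC curve with operating-point statistics.

    ``orientation`` is +1 when larger raw scores indicate the positive
    (arthritic) class and -1 when the biomarker is reduced in arthritic
    animals; thresholds are reported on the raw score scale together with
    the comparison direction that calls an animal positive.
    """

    scores: pd.Series
    labels: pd.Series
    positive_class: str
    orientation: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # raw-scale thresholds matching fpr/tpr points
    auc: float
    auc_ci: tuple[float, float]
    auc_se: float
    chosen_threshold: float | None = None
    threshold_direction: str | None = None  # "<=" or ">="
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    confusion: dict | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        if (np.diff(self.fpr) < -1e-12).any() or (np.diff(self.tpr) < -1e-12).any():
            raise ValueError("ROC points must be monotone nondecreasing")


def composite_score(
    dataset: pd.DataFrame,
    pairs: list[str],
    mode: str = "logistic",
    fit_on: pd.Index | None = None,
    label_col: str = "group",
    ridge_penalty: float = 1e-4,
) -> tuple[pd.Series, CompositeModel]:
    """Score every animal with a composite of the selected pair correlations.

    ``sum`` mode adds the raw correlation values.  ``logistic`` mode fits
    a maximum-likelihood logistic regression of group on the pair values
    using only the rows in ``fit_on`` (default: rows with
    ``cohort == "test"`` when a cohort column exists, else all rows) and
    scores all animals with the linear predictor.  Complete separation —
    expected at these cohort sizes — falls back to a ridge-stabilized fit
    (penalty ``ridge_penalty``) with a warning; the score ordering is all
    the ROC analysis needs.
    """
    if mode not in ("sum", "logistic"):
        raise ValueError("mode must be 'sum' or 'logistic'")
    missing = [p for p in pairs if p not in dataset.columns]
    if missing:
        raise ValueError(f"pairs not in dataset: {missing}")

    if mode == "sum":
        model = CompositeModel(pairs=list(pairs), mode="sum")
        return model.score(dataset), model

    if fit_on is None:
        if "cohort" in dataset.columns:
            fit_on = dataset.index[dataset["cohort"] == "test"]
        else:
            fit_on = dataset.index
    fit = dataset.loc[fit_on]
    x = fit[pairs].to_numpy(dtype=float)
    if np.all(np.ptp(x, axis=0) == 0.0):
        raise ValueError("all predictors constant; logistic fit impossible")
    y = (fit[label_col] == POSITIVE_CLASS).to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("logistic fit needs both classes in the fitting rows")

    from statsmodels.tools.sm_exceptions import (
        ConvergenceWarning,
        PerfectSeparationWarning,
    )

    ridge = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("error", ConvergenceWarning)
            warnings.simplefilter("error", RuntimeWarning)
            res = sm.Logit(y, sm.add_constant(x, has_constant="add")).fit(disp=0)
        if not res.mle_retvals.get("converged", False) or np.abs(res.params).max() > 1e3:
            raise np.linalg.LinAlgError("diverging MLE")
        intercept = float(res.params[0])
        coef = np.asarray(res.params[1:], dtype=float)
    except Exception:
        # complete (or quasi-complete) separation: MLE diverges, but a
        # lightly ridge-penalized fit preserves the score ordering
        ridge = True
        warnings.warn(
            "complete separation in logistic fit; using ridge-stabilized fit",
            RuntimeWarning,
            stacklevel=2,
        )
        clf = LogisticRegression(
            C=1.0 / ridge_penalty, solver="lbfgs", max_iter=10000
        )
        clf.fit(x, y)
        intercept = float(clf.intercept_[0])
        coef = clf.coef_[0].astype(float)

    model = CompositeModel(
        pairs=list(pairs),
        mode="logistic",
        intercept=intercept,
        coefficients=coef,
        ridge_fallback=ridge,
        fit_animal_ids=list(fit.index),
    )
    return model.score(dataset), model


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via placement values."""
    m, n = pos.size, neg.size
    v10 = np.empty(m)
    v01 = np.empty(n)
    for i, s in enumerate(pos):
        v10[i] = (np.sum(s > neg) + 0.5 * np.sum(s == neg)) / n
    for j, s in enumerate(neg):
        v01[j] = (np.sum(pos > s) + 0.5 * np.sum(pos == s)) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def delong_ci(
    pos_scores: np.ndarray, neg_scores: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float], float]:
    """DeLong AUC estimate, confidence interval and standard error."""
    auc, var = _delong_variance(np.asarray(pos_scores), np.asarray(neg_scores))
    se = float(np.sqrt(var))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    lo = max(0.0, auc - zq * se)
    hi = min(1.0, auc + zq * se)
    return auc, (lo, hi), se


def roc_curve(
    scores: pd.Series,
    labels: pd.Series,
    positive_class: str = POSITIVE_CLASS,
) -> RocResult:
    """Empirical ROC over all unique score thresholds.

    The orientation (whether high or low raw scores indicate the positive
    class) is auto-detected from the data so that AUC >= 0.5 on the
    fitting cohort, and recorded for downstream frozen-threshold use.
    """
    scores = pd.Series(scores)
    labels = pd.Series(labels).loc[scores.index]
    classes = set(labels.unique())
    if positive_class not in classes or len(classes) < 2:
        raise ValueError("both classes must be present")

    y = (labels == positive_class).to_numpy(dtype=int)
    s = scores.to_numpy(dtype=float)
    pos, neg = s[y == 1], s[y == 0]

    auc_hi, _ = _delong_variance(pos, neg)
    orientation = 1 if auc_hi >= 0.5 else -1
    oriented = orientation * s

    fpr, tpr, thr = _sk_roc_curve(y, oriented, drop_intermediate=False)
    auc, ci, se = delong_ci(orientation * pos, orientation * neg)
    return RocResult(
        scores=scores,
        labels=labels,
        positive_class=positive_class,
        orientation=orientation,
        fpr=fpr,
        tpr=tpr,
        thresholds=orientation * thr,
        auc=auc,
        auc_ci=ci,
        auc_se=se,
    )


def _operating_stats(
    scores: np.ndarray,
    y: np.ndarray,
    threshold: float,
    orientation: int,
) -> dict:
    """Confusion counts under the convention oriented score >= oriented
    threshold => positive call."""
    calls = orientation * scores >= orientation * threshold - 1e-12
    tp = int(np.sum(calls & (y == 1)))
    fp = int(np.sum(calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))
    tn = int(np.sum(~calls & (y == 0)))
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
    }


def select_threshold(roc: RocResult, rule: str = "youden") -> RocResult:
    """Choose the operating threshold on the fitting cohort.

    The Youden rule maximizes sensitivity + specificity - 1; ties are
    broken toward higher sensitivity.  An animal is called positive when
    its oriented score is >= the oriented threshold.
    """
    if rule != "youden":
        raise ValueError("only the 'youden' rule is implemented")
    finite = np.isfinite(roc.thresholds)
    j = roc.tpr[finite] - roc.fpr[finite]
    candidates = np.flatnonzero(j >= j.max() - 1e-12)
    best = candidates[np.argmax(roc.tpr[finite][candidates])]
    threshold = float(roc.thresholds[finite][best])

    y = (roc.labels == roc.positive_class).to_numpy(dtype=int)
    stats_ = _operating_stats(
        roc.scores.to_numpy(dtype=float), y, threshold, roc.orientation
    )
    roc.chosen_threshold = threshold
    roc.threshold_direction = ">=" if roc.orientation == 1 else "<="
    roc.sensitivity = stats_["sensitivity"]
    roc.specificity = stats_["specificity"]
    roc.ppv = stats_["ppv"]
    roc.npv = stats_["npv"]
    roc.confusion = {k: stats_[k] for k in ("tp", "fp", "tn", "fn")}
    return roc


def external_validate(
    roc: RocResult,
    validation_scores: pd.Series,
    validation_labels: pd.Series,
) -> dict:
    """Frozen-threshold evaluation on an independent validation cohort.

    No refitting of any kind: the threshold, orientation and positive
    class chosen on the test cohort are applied as-is.  Rejects any
    overlap between the two cohorts' animals.
    """
    if roc.chosen_threshold is None:
        raise ValueError("select_threshold must be applied before validation")
    overlap = set(roc.scores.index) & set(pd.Series(validation_scores).index)
    if overlap:
        raise ValueError(f"validation cohort overlaps the test cohort: {sorted(overlap)}")
    scores = pd.Series(validation_scores)
    labels = pd.Series(validation_labels).loc[scores.index]
    y = (labels == roc.positive_class).to_numpy(dtype=int)
    out = _operating_stats(
        scores.to_numpy(dtype=float), y, roc.chosen_threshold, roc.orientation
    )
    out["threshold"] = roc.chosen_threshold
    out["direction"] = roc.threshold_direction
    return out
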