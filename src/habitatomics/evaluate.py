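"""SVM training and model evaluation: ROC/AUC with DeLong confidence
intervals and paired tests, threshold metrics, calibration and decision
curves.

The AUC is the Mann-Whitney estimator; its variance (and the covariance of
two models' AUCs on the same patients) comes from DeLong's structural
components, giving a normal-approximation CI and a two-sided paired test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

__all__ = [
    "HabitatSVM",
    "train_svm",
    "auc_ci_delong",
    "delong_paired_test",
    "threshold_metrics",
    "calibration_curve",
    "decision_curve",
]


# ------------------------------------------------------------------ DeLong


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def auc_ci_delong(
    scores: np.ndarray, labels: np.ndarray, alpha: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC (Mann-Whitney) with a DeLong normal-approximation CI.

    Perfectly ranked scores give SE = 0 and a degenerate CI at the point
    estimate. The CI is clipped to [0, 1].
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    auc, v10, v01 = _structural_components(scores, labels)
    # a class with a single observation contributes no estimable variance
    var = sum(
        v.var(ddof=1) / len(v) for v in (v10, v01) if len(v) > 1
    )
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.5 + alpha / 2.0)
    lo, hi = np.clip([auc - z * se, auc + z * se], 0.0, 1.0)
    return float(auc), (float(lo), float(hi))


def delong_paired_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> float:
    """Two-sided DeLong test of two correlated AUCs on the same patients.

    Identical score vectors (zero-variance difference) return p = 1 by
    convention.
    """
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    labels = np.asarray(labels, int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores and labels must be the same length")
    auc_a, v10_a, v01_a = _structural_components(scores_a, labels)
    auc_b, v10_b, v01_b = _structural_components(scores_b, labels)
    var = 0.0
    for va, vb in ((v10_a, v10_b), (v01_a, v01_b)):
        if len(va) > 1:  # single-observation classes contribute no variance
            s = np.cov(np.vstack([va, vb]), ddof=1)
            var += (s[0, 0] + s[1, 1] - 2 * s[0, 1]) / len(va)
    if var <= 0:
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ------------------------------------------------------------------ SVM


@dataclass
class ModelBundle:
    """A fitted SVM with its hyperparameters, threshold and provenance."""

    model: object
    params: dict
    threshold: float
    cv_auc: float
    seed: int | None
    n_support: list[int] = field(default_factory=list)

    def predict_proba(self, X) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X, float))[:, 1]


class HabitatSVM:
    """RBF-kernel SVM with seeded 5-fold hyperparameter search.

    (C, gamma) maximise mean cross-validated AUC over a small grid (C in
    {0.1, 1, 10, 100}, gamma = scale-heuristic x {0.1, 1, 10}); class
    probabilities come from Platt scaling fitted within folds; the
    operating threshold is the Youden-optimal point of the training ROC
    and is applied unchanged to new cohorts.
    """

    def __init__(self, n_folds: int = 5, random_state: int | None = None):
        self.n_folds = n_folds
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"n_folds": self.n_folds, "random_state": self.random_state}

    def set_params(self, **params) -> "HabitatSVM":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "HabitatSVM":
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if len(np.unique(y)) < 2:
            raise ValueError("labels are degenerate (single class)")
        scale = 1.0 / (X.shape[1] * X.var()) if X.var() > 0 else 1.0
        grid = {
            "C": [0.1, 1.0, 10.0, 100.0],
            "gamma": [scale * f for f in (0.1, 1.0, 10.0)],
        }
        cv = StratifiedKFold(self.n_folds, shuffle=True, random_state=self.random_state)
        search = GridSearchCV(SVC(kernel="rbf"), grid, scoring="roc_auc", cv=cv)
        search.fit(X, y)
        self.model_ = search.best_estimator_
        self.best_params_ = search.best_params_
        self.cv_auc_ = float(search.best_score_)
        # Platt scaling on out-of-fold decision values (sigmoid calibration);
        # calibrating on CV margins avoids the overconfidence of refit margins
        dv = cross_val_predict(
            clone(self.model_), X, y, cv=cv, method="decision_function"
        )
        self._platt = LogisticRegression(C=1e6, solver="lbfgs").fit(dv[:, None], y)
        if self._platt.coef_[0, 0] <= 0:
            # uninformative CV margins can fit a decreasing sigmoid, which
            # would anti-rank the probabilities; calibration must stay
            # monotone increasing in the margin, so refit on refit margins
            dv_train = self.model_.decision_function(X)
            self._platt = LogisticRegression(C=1e6, solver="lbfgs").fit(
                dv_train[:, None], y
            )
        train_scores = self.decision_scores(X)
        self.threshold_ = youden_threshold(train_scores, y)
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        dv = self.model_.decision_function(np.asarray(X, float))
        p1 = self._platt.predict_proba(dv[:, None])[:, 1]
        return np.column_stack([1.0 - p1, p1])

    def decision_scores(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold_).astype(int)

    def bundle(self) -> ModelBundle:
        return ModelBundle(
            model=self.model_,
            params=self.best_params_,
            threshold=self.threshold_,
            cv_auc=self.cv_auc_,
            seed=self.random_state,
            n_support=self.model_.n_support_.tolist(),
        )


def train_svm(X, y, seed: int | None = None, n_folds: int = 5) -> HabitatSVM:
    """Fit the region SVM (see :class:`HabitatSVM`)."""
    return HabitatSVM(n_folds=n_folds, random_state=seed).fit(X, y)


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability threshold maximising sensitivity + specificity - 1."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    order = np.argsort(scores)[::-1]
    s, lab = scores[order], labels[order]
    n_pos, n_neg = lab.sum(), (1 - lab).sum()
    tp = np.cumsum(lab)
    fp = np.cumsum(1 - lab)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    j = sens + spec - 1.0
    best = int(np.argmax(j))
    # the cut predicts positive for scores >= threshold, so place the
    # threshold halfway between the optimal score and the next lower one
    lower = s[best + 1] if best + 1 < len(s) else 0.0
    return float(np.clip((s[best] + lower) / 2.0, 1e-9, 1 - 1e-9))


# ------------------------------------------------------------- metrics


def threshold_metrics(scores, labels, threshold: float) -> dict:
    """Accuracy/sensitivity/specificity/PPV/NPV and the confusion matrix."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    n = tp + fp + fn + tn

    def _safe(a, b):
        return a / b if b else np.nan

    return {
        "accuracy": (tp + tn) / n,
        "sensitivity": _safe(tp, tp + fn),
        "specificity": _safe(tn, tn + fp),
        "ppv": _safe(tp, tp + fp),
        "npv": _safe(tn, tn + fn),
        "confusion_matrix": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


def calibration_curve(scores, labels, n_bins: int = 10) -> dict:
    """Decile-binned predicted vs observed frequencies + recalibration fit.

    The recalibration slope/intercept come from a logistic regression of
    the outcome on logit(score); slope near 1 and intercept near 0 indicate
    good calibration.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must be probabilities in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)
    points = []
    for b in range(n_bins):
        sel = idx == b
        count = int(sel.sum())
        points.append(
            {
                "bin_mid": float((edges[b] + edges[b + 1]) / 2.0),
                "mean_predicted": float(scores[sel].mean()) if count else np.nan,
                "observed_frequency": float(labels[sel].mean()) if count else np.nan,
                "count": count,
            }
        )
    eps = 1e-9
    logit = np.log(np.clip(scores, eps, 1 - eps) / np.clip(1 - scores, eps, 1 - eps))
    if len(np.unique(labels)) == 2 and np.ptp(logit) > 0:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1e9, solver="lbfgs").fit(logit[:, None], labels)
        slope = float(lr.coef_[0, 0])
        intercept = float(lr.intercept_[0])
    else:
        slope, intercept = np.nan, np.nan
    return {"points": points, "slope": slope, "intercept": intercept}


def decision_curve(scores, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit NB(t) = TP/n - (FP/n) * t/(1-t) per threshold.

    Includes the treat-all (prevalence - (1-prevalence) * t/(1-t)) and
    treat-none (0) references. Thresholds at or above 1 are rejected.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(labels)
    prevalence = labels.mean()
    rows = []
    for t in thresholds:
        pred = scores >= t
        tp = float((pred & (labels == 1)).sum())
        fp = float((pred & (labels == 0)).sum())
        odds = t / (1.0 - t)
        rows.append(
            {
                "threshold": t,
                "net_benefit": tp / n - fp / n * odds,
                "treat_all": prevalence - (1 - prevalence) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)
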