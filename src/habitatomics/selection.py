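"""Feature-reduction funnel: ICC reproducibility -> z-score -> Pearson
redundancy pruning -> LASSO.

Each stage only removes features, so the surviving sets are nested
(LASSO subset of Pearson subset of ICC subset of all). The z-score
parameters come from the training cohort only and are applied unchanged to
the test cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "icc_per_feature",
    "ICCFilter",
    "zscore_fit_apply",
    "pearson_prune",
    "CorrelationPruner",
    "LassoSelector",
    "lasso_select",
    "SelectionReport",
    "select_features",
]


def _icc21(y1: np.ndarray, y2: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Mean-squares decomposition for n subjects x k=2 raters:
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    """
    Y = np.column_stack([y1, y2]).astype(float)
    n, k = Y.shape
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or (msr == 0 and mse == 0):
        return np.nan  # no between-subject variance: agreement undefined
    return float((msr - mse) / denom)


def icc_per_feature(matrix_r1: pd.DataFrame, matrix_r2: pd.DataFrame) -> pd.Series:
    """ICC(2,1) per feature between two readers' feature matrices.

    Undefined ICCs (zero between-subject variance) are returned as NaN and
    should be treated as failing any retention threshold.
    """
    if list(matrix_r1.columns) != list(matrix_r2.columns):
        raise ValueError("reader matrices must share columns")
    if not matrix_r1.index.equals(matrix_r2.index):
        raise ValueError("reader matrices must share patients (index)")
    if len(matrix_r1) < 3:
        raise ValueError("need at least 3 patients for ICC")
    out = {
        col: _icc21(matrix_r1[col].to_numpy(), matrix_r2[col].to_numpy())
        for col in matrix_r1.columns
    }
    return pd.Series(out, name="icc")


class ICCFilter:
    """Keep features whose two-reader ICC(2,1) >= threshold (default 0.75)."""

    def __init__(self, threshold: float = 0.75):
        self.threshold = threshold

    def fit(self, matrix_r1: pd.DataFrame, matrix_r2: pd.DataFrame) -> "ICCFilter":
        self.icc_ = icc_per_feature(matrix_r1, matrix_r2)
        self.support_ = (self.icc_ >= self.threshold).fillna(False)
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        kept = [c for c in matrix.columns if self.support_.get(c, False)]
        return matrix[kept]


def zscore_fit_apply(
    train: pd.DataFrame, test: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Standardise columns to mean 0, SD 1 (population SD, ddof=0).

    Parameters are fitted on the training matrix and applied unchanged to
    the test matrix. Returns (train_z, test_z, params) where params has
    ``mean``/``sd`` rows per feature. Zero-variance training columns raise,
    naming the offending features.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training rows")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance features: {dead[:10]}")
    train_z = (train - mean) / sd
    test_z = (test - mean) / sd if test is not None else None
    params = pd.DataFrame({"mean": mean, "sd": sd}).T
    return train_z, test_z, params


def pearson_prune(
    matrix: pd.DataFrame, threshold: float = 0.9, raw: pd.DataFrame | None = None
) -> list[str]:
    """Greedy redundancy pruning: drop any feature with |r| > threshold
    against an already-kept one.

    Columns are visited in order of decreasing raw-feature variance (ties
    broken by column name), so of a correlated pair the more variable
    feature survives. Returns the kept column names in visiting order.
    """
    ref = raw if raw is not None else matrix
    variances = ref.var(axis=0, ddof=1)
    order = sorted(matrix.columns, key=lambda c: (-variances[c], c))
    corr = matrix[order].corr().abs().to_numpy()
    kept_idx: list[int] = []
    for i in range(len(order)):
        if all(corr[i, j] <= threshold or np.isnan(corr[i, j]) for j in kept_idx):
            kept_idx.append(i)
    return [order[i] for i in kept_idx]


class CorrelationPruner:
    """Transformer wrapper over :func:`pearson_prune`."""

    def __init__(self, threshold: float = 0.9):
        self.threshold = threshold

    def fit(self, matrix: pd.DataFrame, raw: pd.DataFrame | None = None) -> "CorrelationPruner":
        self.kept_ = pearson_prune(matrix, self.threshold, raw=raw)
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return matrix[self.kept_]

    def fit_transform(self, matrix: pd.DataFrame, raw: pd.DataFrame | None = None) -> pd.DataFrame:
        return self.fit(matrix, raw=raw).transform(matrix)


class LassoSelector:
    """L1-penalised logistic regression feature selector.

    The penalty strength is chosen to minimise mean cross-validated
    binomial deviance over seeded stratified folds; the support is the set
    of non-zero coefficients at the chosen penalty. ``lambda_`` is the
    selected regularisation strength (1/C).

    The penalty grid spans lambda in [0.1, 100] (C in [0.01, 10]): weaker
    penalties approach the unpenalised fit, which is never optimal for
    selection and makes the coordinate-descent solver crawl on separable
    data.
    """

    def __init__(
        self,
        n_folds: int = 5,
        n_lambdas: int = 25,
        c_range: tuple[float, float] = (-2.0, 1.0),  # log10 bounds of the C grid
        random_state: int | None = None,
        max_iter: int = 5000,
    ):
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.c_range = c_range
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "LassoSelector":
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("labels are degenerate (single class)")
        if min(np.bincount(y.astype(int))) < self.n_folds:
            raise ValueError("too few patients per class for the fold count")
        cv = StratifiedKFold(self.n_folds, shuffle=True, random_state=self.random_state)
        model = LogisticRegressionCV(
            Cs=np.logspace(self.c_range[0], self.c_range[1], self.n_lambdas),
            cv=cv,
            penalty="l1",
            solver="liblinear",
            scoring="neg_log_loss",
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else None
        model.fit(np.asarray(X, float), y)
        coef = model.coef_.ravel()
        self.coef_ = pd.Series(coef, index=cols) if cols else pd.Series(coef)
        self.C_ = float(model.C_[0])
        self.lambda_ = 1.0 / self.C_
        self.support_ = self.coef_[self.coef_ != 0].index.tolist()
        self.model_ = model
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.support_]


def lasso_select(
    train_z: pd.DataFrame, labels: np.ndarray, n_folds: int = 5, seed: int | None = None
) -> tuple[list[str], pd.Series, float]:
    """Functional wrapper: returns (support, coefficients, lambda*)."""
    sel = LassoSelector(n_folds=n_folds, random_state=seed).fit(train_z, labels)
    return sel.support_, sel.coef_, sel.lambda_


@dataclass
class SelectionReport:
    """Everything needed to audit/replay a selection run."""

    icc: pd.Series | None
    survivors_icc: list[str]
    survivors_pearson: list[str]
    survivors_lasso: list[str]
    lasso_coef: pd.Series
    lambda_: float
    zscore_params: pd.DataFrame
    seed: int | None

    def stage_counts(self) -> dict[str, int]:
        return {
            "icc": len(self.survivors_icc),
            "pearson": len(self.survivors_pearson),
            "lasso": len(self.survivors_lasso),
        }


def select_features(
    train: pd.DataFrame,
    labels: np.ndarray,
    test: pd.DataFrame | None = None,
    train_r2: pd.DataFrame | None = None,
    icc_threshold: float = 0.75,
    pearson_threshold: float = 0.9,
    n_folds: int = 5,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, SelectionReport]:
    """Run the full funnel on one region's feature matrix.

    The ICC stage runs only when a second-reader matrix ``train_r2`` is
    supplied (covering the patients present in its index).
    """
    icc = None
    survivors = list(train.columns)
    if train_r2 is not None:
        common = train.index.intersection(train_r2.index)
        icc_filter = ICCFilter(icc_threshold).fit(
            train.loc[common, train_r2.columns], train_r2.loc[common]
        )
        icc = icc_filter.icc_
        survivors = [c for c in survivors if icc_filter.support_.get(c, False)]
    survivors_icc = list(survivors)

    # constant columns cannot be z-scored; they carry no signal and are dropped
    sub = train[survivors]
    sd = sub.std(axis=0, ddof=0)
    survivors = [c for c in survivors if sd[c] > 0]
    train_z, test_z, params = zscore_fit_apply(
        train[survivors], test[survivors] if test is not None else None
    )
    kept = pearson_prune(train_z, pearson_threshold, raw=train[survivors])
    sel = LassoSelector(n_folds=n_folds, random_state=seed).fit(train_z[kept], labels)
    report = SelectionReport(
        icc=icc,
        survivors_icc=survivors_icc,
        survivors_pearson=kept,
        survivors_lasso=sel.support_,
        lasso_coef=sel.coef_,
        lambda_=sel.lambda_,
        zscore_params=params,
        seed=seed,
    )
    train_out = train_z[sel.support_]
    test_out = test_z[sel.support_] if test_z is not None else None
    return train_out, test_out, report
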