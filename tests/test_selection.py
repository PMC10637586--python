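"""ICC, z-scoring, Pearson pruning and LASSO selection."""

import numpy as np
import pandas as pd
import pytest

from habitatomics.selection import (
    ICCFilter,
    LassoSelector,
    icc_per_feature,
    pearson_prune,
    select_features,
    zscore_fit_apply,
)


def icc21_anova_oracle(y1, y2):
    """Independent two-way ANOVA mean-squares computation of ICC(2,1)."""
    Y = np.column_stack([y1, y2])
    n, k = Y.shape
    grand = Y.mean()
    msr = k * ((Y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((Y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_readers_icc_one(self):
        rng = np.random.default_rng(0)
        m1 = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        icc = icc_per_feature(m1, m1.copy())
        assert np.allclose(icc.values, 1.0)

    def test_independent_noise_icc_near_zero(self):
        rng = np.random.default_rng(1)
        m1 = pd.DataFrame(rng.normal(size=(50, 6)))
        m2 = pd.DataFrame(rng.normal(size=(50, 6)))
        m2.columns = m1.columns
        assert np.all(np.abs(icc_per_feature(m1, m2).values) < 0.3)

    def test_worked_table_matches_anova_oracle(self):
        y1 = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
        y2 = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])
        m1 = pd.DataFrame({"f": y1})
        m2 = pd.DataFrame({"f": y2})
        got = icc_per_feature(m1, m2)["f"]
        assert got == pytest.approx(icc21_anova_oracle(y1, y2), abs=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        subject_effect = rng.normal(0, 2, 12)
        y1 = subject_effect + rng.normal(0, 1, 12)
        y2 = subject_effect + 0.5 + rng.normal(0, 1, 12)
        long = pd.DataFrame(
            {
                "subject": np.tile(np.arange(12), 2),
                "rater": np.repeat(["r1", "r2"], 12),
                "score": np.concatenate([y1, y2]),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        )
        # two-way random effects, absolute agreement, single rater
        match = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        ref_icc = float(ref.loc[match, "ICC"].iloc[0])
        got = icc_per_feature(pd.DataFrame({"f": y1}), pd.DataFrame({"f": y2}))["f"]
        assert got == pytest.approx(ref_icc, abs=1e-8)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        subject = rng.normal(0, 2, 20)
        y1 = subject + rng.normal(0, 0.5, 20)
        y2 = subject + rng.normal(0, 0.5, 20)
        a = icc_per_feature(pd.DataFrame({"f": y1}), pd.DataFrame({"f": y2}))["f"]
        b = icc_per_feature(
            pd.DataFrame({"f": 3.0 * y1 + 7.0}), pd.DataFrame({"f": 3.0 * y2 + 7.0})
        )["f"]
        assert a == pytest.approx(b, abs=1e-10)

    def test_zero_between_subject_variance_is_nan_and_fails_filter(self):
        m1 = pd.DataFrame({"f": [1.0, 1.0, 1.0, 1.0]})
        m2 = pd.DataFrame({"f": [1.0, 1.0, 1.0, 1.0]})
        icc = icc_per_feature(m1, m2)
        assert np.isnan(icc["f"])
        filt = ICCFilter(0.75).fit(m1, m2)
        assert not filt.support_["f"]

    def test_too_few_patients_raises(self):
        m = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ValueError):
            icc_per_feature(m, m)


class TestZScore:
    def test_closed_form(self):
        train = pd.DataFrame({"f": [1.0, 3.0]})
        train_z, _, params = zscore_fit_apply(train)
        assert np.allclose(train_z["f"], [-1.0, 1.0])  # population SD convention
        assert params.loc["mean", "f"] == 2.0 and params.loc["sd", "f"] == 1.0

    def test_test_equal_train_same_zscores(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        train_z, test_z, _ = zscore_fit_apply(train, train.copy())
        assert np.allclose(train_z.values, test_z.values)

    def test_round_trip_inverse(self):
        rng = np.random.default_rng(1)
        train = pd.DataFrame(rng.normal(5, 3, size=(20, 2)), columns=["a", "b"])
        train_z, _, params = zscore_fit_apply(train)
        back = train_z * params.loc["sd"] + params.loc["mean"]
        assert np.allclose(back.values, train.values, atol=1e-12)

    def test_zero_variance_names_column(self):
        train = pd.DataFrame({"dead": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="dead"):
            zscore_fit_apply(train)


class TestPearsonPrune:
    def test_duplicate_column_one_survives(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        m = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=30)})
        kept = pearson_prune(m, 0.9)
        assert sum(col in kept for col in ("a", "b")) == 1
        assert "c" in kept

    def test_orthogonal_columns_all_survive(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(200, 5)))
        m.columns = list("abcde")
        assert len(pearson_prune(m, 0.9)) == 5

    def test_matches_independent_greedy_oracle(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(40, 4))
        m = pd.DataFrame(
            np.column_stack(
                [
                    base[:, 0],
                    base[:, 0] * 2 + rng.normal(0, 0.01, 40),
                    base[:, 1],
                    base[:, 1] + rng.normal(0, 0.05, 40),
                    base[:, 2],
                    base[:, 3],
                    base[:, 2] * -1.5 + rng.normal(0, 0.02, 40),
                    rng.normal(size=40),
                    rng.normal(size=40),
                    base[:, 0] + base[:, 1],
                ]
            ),
            columns=[f"f{i}" for i in range(10)],
        )
        # independent re-implementation of the same greedy rule
        order = sorted(m.columns, key=lambda c: (-m[c].var(ddof=1), c))
        corr = m[order].corr().abs()
        kept_oracle = []
        for col in order:
            if all(corr.loc[col, other] <= 0.9 for other in kept_oracle):
                kept_oracle.append(col)
        assert pearson_prune(m, 0.9) == kept_oracle


class TestLasso:
    def test_huge_penalty_empty_support(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(60, 10)))
        X.columns = [f"f{i}" for i in range(10)]
        y = rng.integers(0, 2, 60)
        sel = LassoSelector(n_lambdas=1, c_range=(-6.0, -6.0), random_state=0).fit(X, y)
        assert sel.support_ == []

    def test_informative_features_recovered(self):
        rng = np.random.default_rng(1)
        n = 200
        informative = rng.normal(size=(n, 5))
        noise = rng.normal(size=(n, 45))
        logit = informative.sum(axis=1) * 1.0
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        X = pd.DataFrame(
            np.column_stack([informative, noise]),
            columns=[f"inf{i}" for i in range(5)] + [f"noise{i}" for i in range(45)],
        )
        sel = LassoSelector(random_state=0).fit(X, y)
        assert sum(f.startswith("inf") for f in sel.support_) >= 4

    def test_degenerate_labels_raise(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(ValueError):
            LassoSelector().fit(X, np.zeros(20, dtype=int))


class TestFunnel:
    def test_stage_nesting(self):
        rng = np.random.default_rng(4)
        n = 60
        subject = rng.normal(size=(n, 12))
        cols = [f"f{i}" for i in range(12)]
        train = pd.DataFrame(subject, columns=cols)
        train["f11"] = train["f0"] * 1.01 + rng.normal(0, 0.01, n)  # redundant pair
        r2 = train + rng.normal(0, 0.2, train.shape)  # mostly reproducible readers
        y = (train["f0"] + rng.normal(0, 1.2, n) > 0).astype(int).to_numpy()
        _, _, report = select_features(train, y, train_r2=r2, seed=0)
        assert set(report.survivors_lasso) <= set(report.survivors_pearson)
        assert set(report.survivors_pearson) <= set(report.survivors_icc)
        assert set(report.survivors_icc) <= set(train.columns)

    def test_replayable_from_seed(self):
        rng = np.random.default_rng(5)
        train = pd.DataFrame(rng.normal(size=(50, 8)), columns=[f"f{i}" for i in range(8)])
        y = rng.integers(0, 2, 50)
        y[:5] = 1
        y[-5:] = 0
        _, _, a = select_features(train, y, seed=9)
        _, _, b = select_features(train, y, seed=9)
        assert a.survivors_lasso == b.survivors_lasso
        assert a.lambda_ == b.lambda_
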