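"""Feature-selection cascade: ICC, univariate tests, Spearman pruning, mRMR,
LASSO, nesting and train-only discipline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from habitat_radiomics.selection import (
    SelectionConfig,
    icc_2_1,
    lasso_select,
    mrmr_select,
    run_cascade,
    spearman_prune,
    univariate_filter,
)


class TestIcc:
    def test_perfect_agreement(self, rng):
        x = rng.normal(size=20)
        assert icc_2_1(x, x) == pytest.approx(1.0)

    def test_constant_offset_penalized(self, rng):
        x = rng.normal(size=20)
        assert icc_2_1(x, x + 5.0) < 1.0  # absolute agreement, not consistency

    def test_six_subject_table_matches_pingouin(self):
        """Hand table checked against the reference ICC2 implementation."""
        pingouin = pytest.importorskip("pingouin")
        r1 = np.array([9.0, 6.0, 8.0, 7.0, 10.0, 6.0])
        r2 = np.array([2.0, 1.0, 4.0, 1.0, 5.0, 2.0])
        ours = icc_2_1(r1, r2)
        df = pd.DataFrame(
            {
                "subject": list(range(6)) * 2,
                "rater": ["a"] * 6 + ["b"] * 6,
                "score": np.r_[r1, r2],
            }
        )
        ref = pingouin.intraclass_corr(df, "subject", "rater", "score")
        row = ref["Type"].astype(str).str.contains("A,1|ICC2", regex=True)
        expected = ref.loc[row, "ICC"].iloc[0]
        assert ours == pytest.approx(expected, abs=1e-9)

    def test_vectorized_matches_scalar(self, rng):
        a = rng.normal(size=(12, 5))
        b = a + rng.normal(0, 0.3, size=(12, 5))
        vec = icc_2_1(a, b)
        for j in range(5):
            assert vec[j] == pytest.approx(icc_2_1(a[:, j], b[:, j]))

    def test_zero_between_subject_variance_convention(self):
        a = np.zeros(6)
        b = np.zeros(6)
        assert icc_2_1(a, b) == 0.0


def _table(rng, n=87, p=30):
    y = pd.Series(rng.integers(0, 2, size=n), index=[f"p{i}" for i in range(n)])
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        index=y.index,
        columns=[f"f{i}" for i in range(p)],
    )
    return X, y


class TestUnivariateFilter:
    def test_planted_feature_retained(self, rng):
        X, y = _table(rng)
        X["signal"] = y + rng.normal(0, 0.1, size=len(y))
        survivors, frame = univariate_filter(X, y)
        assert "signal" in survivors
        assert frame.loc["signal", "p"] < 1e-6

    def test_constant_feature_excluded_with_reason(self, rng):
        X, y = _table(rng, p=3)
        X["flat"] = 1.0
        survivors, frame = univariate_filter(X, y)
        assert "flat" not in survivors
        assert frame.loc["flat", "test"] == "excluded"

    def test_type_one_error_rate_on_noise(self, rng):
        X, y = _table(rng, n=87, p=400)
        survivors, _ = univariate_filter(X, y)
        rate = len(survivors) / 400
        # binomial(400, 0.05): 3 sigma ~ 0.033
        assert 0.017 < rate < 0.083

    def test_normality_gates_test_choice(self, rng):
        X, y = _table(rng, n=200, p=1)
        X["skewed"] = np.exp(rng.normal(size=200) * 2)
        _, frame = univariate_filter(X, y)
        assert frame.loc["skewed", "test"] == "mannwhitney_u"
        # exact normal quantiles pass Shapiro-Wilk decisively in both classes
        X2 = X[["f0"]].copy()
        q = stats.norm.ppf((np.arange(200) + 0.5) / 200)
        rng.shuffle(q)
        X2["f0"] = q
        _, frame2 = univariate_filter(X2, y)
        assert frame2.loc["f0", "test"] == "welch_t"


class TestSpearmanPrune:
    def test_duplicated_column_keeps_one(self, rng):
        X, y = _table(rng, p=4)
        X["dup"] = X["f0"]
        prio = pd.Series({c: i for i, c in enumerate(X.columns)})
        kept = spearman_prune(X, list(X.columns), 0.9, prio)
        assert ("f0" in kept) != ("dup" in kept)

    def test_monotone_transform_pruned(self, rng):
        X, y = _table(rng, p=2)
        X["exp_f0"] = np.exp(X["f0"])  # |rho| = 1 with f0
        kept = spearman_prune(X, list(X.columns), 0.9)
        assert ("f0" in kept) != ("exp_f0" in kept)

    def test_no_kept_pair_above_cutoff(self, rng):
        n = 60
        base = rng.normal(size=(n, 3))
        X = pd.DataFrame(
            np.column_stack([base, base + rng.normal(0, 0.05, size=(n, 3))]),
            columns=list("abcdef"),
        )
        kept = spearman_prune(X, list(X.columns), 0.9)
        rho = X[kept].corr(method="spearman").to_numpy()
        off = rho[~np.eye(len(kept), dtype=bool)]
        assert np.all(np.abs(off) <= 0.9)

    def test_priority_keeps_lowest_p_member(self, rng):
        X, y = _table(rng, p=2)
        X["twin"] = X["f0"] + rng.normal(0, 0.01, size=len(X))
        prio = pd.Series({"f0": 0.5, "twin": 0.001, "f1": 0.9})
        kept = spearman_prune(X, ["f0", "twin", "f1"], 0.9, prio)
        assert "twin" in kept and "f0" not in kept

    def test_hand_made_structure_matches_greedy_oracle(self, rng):
        """Six features with a planted correlation structure: survivors equal
        the greedy walk done by hand (visit by priority, drop if |rho| > 0.9
        with any kept)."""
        n = 200
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        X = pd.DataFrame(
            {
                "a": z1,
                "b": z1 + rng.normal(0, 0.01, n),  # twin of a
                "c": z2,
                "d": z2 + rng.normal(0, 0.01, n),  # twin of c
                "e": rng.normal(size=n),
                "f": z1 + z2,  # correlated but below cutoff with both
            }
        )
        prio = pd.Series({"a": 1, "b": 2, "c": 3, "d": 4, "e": 5, "f": 6})
        kept = spearman_prune(X, list(X.columns), 0.9, prio)
        assert kept == ["a", "c", "e", "f"]


class TestMrmr:
    def test_single_candidate_selected(self, rng):
        X, y = _table(rng, p=1)
        assert mrmr_select(X, y, 1) == ["f0"]

    def test_duplicate_of_best_loses_to_independent_signal(self, rng):
        """The FCQ quotient divides the duplicate's relevance by redundancy
        ~1, so an independent feature of comparable relevance wins the
        second slot."""
        X, y = _table(rng, p=3)
        X["best"] = y + rng.normal(0, 0.4, size=len(y))
        X["best_copy"] = X["best"].to_numpy()
        X["alt"] = y + rng.normal(0, 0.4, size=len(y))
        picked = mrmr_select(X, y, 2)
        # the duplicate pair must never fill both slots: redundancy 1 halves
        # nothing but the quotient penalizes the copy below the alternative
        assert set(picked) != {"best", "best_copy"}
        assert "alt" in picked

    def test_two_picks_match_exhaustive_oracle(self, rng):
        X, y = _table(rng, n=100, p=5)
        X["s"] = y + rng.normal(0, 0.5, size=len(y))
        picked = mrmr_select(X, y, 2)

        def f_stat(col):
            g0, g1 = X[col][y == 0], X[col][y == 1]
            return stats.f_oneway(g0, g1).statistic

        first = max(X.columns, key=lambda c: (f_stat(c), 0))
        rest = [c for c in X.columns if c != first]
        second = max(
            rest,
            key=lambda c: f_stat(c) / max(abs(np.corrcoef(X[c], X[first])[0, 1]), 1e-12),
        )
        assert picked == [first, second]

    def test_k_above_available_warns_and_selects_all(self, rng):
        X, y = _table(rng, p=3)
        with pytest.warns(UserWarning):
            out = mrmr_select(X, y, 10)
        assert sorted(out) == sorted(X.columns)


class TestLasso:
    def test_huge_penalty_limit_gives_empty_set(self, rng):
        """At strong penalties all coefficients are zero; if the deviance
        optimum lands there the survivor set is empty with a warning."""
        X, y = _table(rng, n=40, p=5)  # pure noise: null model wins
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(l1_ratio=1.0, C=1e-6, solver="liblinear")
        clf.fit(X.to_numpy(), y.to_numpy())
        assert np.all(clf.coef_ == 0.0)

    def test_planted_signal_survives_across_seeds(self, rng):
        hits = 0
        for seed in range(10):
            local = np.random.default_rng(seed)
            y = pd.Series(local.integers(0, 2, size=80), index=[f"p{i}" for i in range(80)])
            X = pd.DataFrame(
                local.normal(size=(80, 10)),
                index=y.index,
                columns=[f"n{i}" for i in range(10)],
            )
            X["signal"] = y + local.normal(0, 0.3, size=80)
            X = (X - X.mean()) / X.std()
            survivors, _ = lasso_select(X, y, folds=5, seed=seed)
            hits += "signal" in survivors
        assert hits >= 9

    def test_weak_penalty_matches_unpenalized_logistic(self, rng):
        import statsmodels.api as sm
        from sklearn.linear_model import LogisticRegression

        y = rng.integers(0, 2, size=300)
        X = rng.normal(size=(300, 3))
        X[:, 0] += 0.8 * y
        clf = LogisticRegression(l1_ratio=1.0, C=1e6, solver="liblinear", max_iter=5000)
        clf.fit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(clf.coef_.ravel(), ref.params[1:], atol=0.02)

    def test_deterministic_given_seed(self, rng):
        X, y = _table(rng, n=60, p=8)
        X["signal"] = y + rng.normal(0, 0.4, size=len(y))
        a, pa = lasso_select(X, y, folds=5, seed=3)
        b, pb = lasso_select(X, y, folds=5, seed=3)
        assert a == b and pa["best_index"] == pb["best_index"]


class TestCascade:
    def _cohort_tables(self, rng, n=60, p=40):
        ids = [f"p{i}" for i in range(n)]
        y = pd.Series(rng.integers(0, 2, size=n), index=ids)
        X = pd.DataFrame(
            rng.normal(size=(n, p)), index=ids, columns=[f"f{i}" for i in range(p)]
        )
        X["signal"] = y + rng.normal(0, 0.3, size=n)
        X2 = X + rng.normal(0, 0.05, size=X.shape)  # reproducible across raters
        X2["f0"] = rng.normal(size=n)  # f0 is not reproducible
        return X, X2, y, ids[:42]

    def test_stage_nesting_and_icc_behaviour(self, rng):
        X, X2, y, train = self._cohort_tables(rng)
        report = run_cascade(X, X2, y, train, SelectionConfig(mrmr_k=10, lasso_folds=5), "t")
        stages = ["complete", "icc", "univariate", "spearman", "mrmr", "lasso"]
        for a, b in zip(stages, stages[1:]):
            assert set(report.stages[b]) <= set(report.stages[a])
        assert "f0" not in report.stages["icc"]  # failed reproducibility
        assert "signal" in report.selected

    def test_missing_columns_dropped_upfront(self, rng):
        X, X2, y, train = self._cohort_tables(rng, p=10)
        X.loc[train[0], "f3"] = np.nan
        report = run_cascade(X, X2, y, train, SelectionConfig(mrmr_k=5, lasso_folds=5), "t")
        assert "f3" not in report.stages["complete"]

    def test_unknown_train_ids_rejected(self, rng):
        X, X2, y, train = self._cohort_tables(rng, p=5)
        with pytest.raises(ValueError):
            run_cascade(X, X2, y, train + ["ghost"], SelectionConfig(), "t")

    def test_statistics_computed_on_train_rows_only(self, rng):
        """Flipping test-split values must not change any selection output."""
        X, X2, y, train = self._cohort_tables(rng, p=15)
        cfg = SelectionConfig(mrmr_k=8, lasso_folds=5)
        r1 = run_cascade(X, X2, y, train, cfg, "t")
        X_poison = X.copy()
        test_ids = [i for i in X.index if i not in train]
        X_poison.loc[test_ids] = 999.0
        r2 = run_cascade(X_poison, X2, y, train, cfg, "t")
        assert r1.stages == r2.stages
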