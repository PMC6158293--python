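"""Split, down-sampling, LASSO, CV, model selection, threshold choice."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from patternsurv.features import Horizon, build_feature_matrix
from patternsurv.encoding import encode_cohort
from patternsurv.mining import MiningParams, mine_patterns
from patternsurv.model import (SplitSpec, choose_threshold, cross_validate,
                               downsample_majority, fit_lasso_logistic,
                               select_model, split_train_test)
from conftest import make_record, simple_raw_visits


def _uniform_cohort(n=100, frac_male=0.5):
    records = []
    for i in range(n):
        sex = "male" if i < int(n * frac_male) else "female"
        records.append(make_record(f"P{i:03d}", sex=sex, deceased=True,
                                   outcome_day=400,
                                   visits=simple_raw_visits([0, 60])))
    return records


class TestSplit:
    def test_stratified_counts(self):
        records = _uniform_cohort(100)  # all in one survival subgroup
        train, test = split_train_test(records, SplitSpec(seed=0))
        assert len(train) == 75 and len(test) == 25
        assert not set(train) & set(test)
        males = {r.patient_id for r in records if r.sex == "male"}
        assert 37 <= len(males & set(train)) <= 38

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(_uniform_cohort(100)[:1], SplitSpec())

    def test_deterministic(self):
        records = _uniform_cohort(60)
        assert split_train_test(records, SplitSpec(seed=4)) == \
            split_train_test(records, SplitSpec(seed=4))

    def test_small_stratum_merged_with_warning(self):
        records = _uniform_cohort(40, frac_male=0.95)  # 2 females only
        with pytest.warns(UserWarning, match="merged"):
            train, test = split_train_test(records, SplitSpec(seed=0))
        assert len(train) + len(test) == 40

    def test_class_proportions_preserved(self, default_cohort):
        """Train and test label proportions differ by < 5 percentage points."""
        train_ids, test_ids = split_train_test(default_cohort, SplitSpec(seed=2))
        sequences = encode_cohort(default_cohort, None, "rano")
        mp = MiningParams(0.5, 60, 1, 1)
        by_id = {r.patient_id: r for r in default_cohort}
        fracs = []
        for ids in (train_ids, test_ids):
            recs = [by_id[i] for i in ids]
            _, y, _ = build_feature_matrix(recs, sequences, [], mp, Horizon(6))
            fracs.append(y.mean())
        assert abs(fracs[0] - fracs[1]) < 0.05


class TestDownsample:
    def test_majority_reduced(self):
        labels = np.array([0] * 190 + [1] * 10)
        idx = downsample_majority(labels, seed=0)
        assert len(idx) == 20
        assert labels[idx].sum() == 10

    def test_balanced_identity(self):
        labels = np.array([0, 1, 0, 1])
        assert list(downsample_majority(labels, seed=0)) == [0, 1, 2, 3]

    def test_deterministic(self):
        labels = np.array([0] * 50 + [1] * 10)
        assert list(downsample_majority(labels, seed=3)) == \
            list(downsample_majority(labels, seed=3))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            downsample_majority(np.ones(10), seed=0)


class TestLassoLogistic:
    def test_zero_coefficient_or_is_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.integers(0, 2, 200),
                          "noise": rng.integers(0, 2, 200)})
        y = X["a"].to_numpy()
        fit = fit_lasso_logistic(X, y, lam=0.05)
        ors = fit.adjusted_odds_ratios
        unselected = [n for n in fit.feature_names if n not in fit.selected]
        for name in unselected:
            assert ors[name] == 1.0

    def test_huge_lambda_gives_intercept_only(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.integers(0, 2, 100)})
        y = rng.integers(0, 2, 100)
        fit = fit_lasso_logistic(X, y, lam=50.0)
        assert fit.selected == []

    def test_separating_feature_selected_with_positive_sign(self):
        """Matches the sign of an unpenalized logistic fit on the same data."""
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"signal": np.repeat([1, 0], 50),
                          "noise": rng.integers(0, 2, 100)})
        y = np.repeat([1, 0], 50)
        fit = fit_lasso_logistic(X, y, lam=0.02)
        assert "signal" in fit.selected
        assert fit.coefficients[0] > 0
        unpen = LogisticRegression(C=np.inf, max_iter=2000).fit(X, y)
        assert np.sign(unpen.coef_[0][0]) == np.sign(fit.coefficients[0])

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            fit_lasso_logistic(pd.DataFrame({"a": [1, 0]}), np.array([1, 2]), 0.1)

    def test_monotone_regularization_path(self, default_cohort):
        records = default_cohort[:80]
        sequences = encode_cohort(records, None, "rano")
        mp = MiningParams(0.4, 60, 2, 2)
        patterns = mine_patterns(
            {r.patient_id: sequences[r.patient_id] for r in records}, mp)
        X, y, _ = build_feature_matrix(records, sequences, patterns, mp, Horizon(6))
        counts = [len(fit_lasso_logistic(X, y, lam).selected)
                  for lam in (0.001, 0.003, 0.01, 0.03, 0.1)]
        assert counts == sorted(counts, reverse=True)


class TestChooseThreshold:
    def test_perfectly_separated_midpoint(self):
        scores = [0.1] * 5 + [0.9] * 5
        labels = [0] * 5 + [1] * 5
        assert choose_threshold(scores, labels) == pytest.approx(0.5)

    def test_symmetric_scores_near_half(self):
        rng = np.random.default_rng(0)
        pos = np.clip(rng.normal(0.7, 0.1, 400), 0, 1)
        neg = np.clip(rng.normal(0.3, 0.1, 400), 0, 1)
        t = choose_threshold(np.concatenate([pos, neg]),
                             np.array([1] * 400 + [0] * 400))
        assert 0.4 < t < 0.6

    def test_degenerate_scores_default(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert choose_threshold([0.5, 0.5], [0, 1]) == 0.5


def _labeled_matrix(default_cohort, months=6):
    records = default_cohort
    sequences = encode_cohort(records, None, "rano")
    mp = MiningParams(0.35, 60, 2, 2)
    patterns = mine_patterns(sequences, mp)
    X, y, meta = build_feature_matrix(records, sequences, patterns, mp,
                                      Horizon(months))
    return X, y, meta, mp, patterns


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def matrix(self, default_cohort):
        return _labeled_matrix(default_cohort)

    def test_signal_recovery_auc(self, matrix):
        X, y, *_ = matrix
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auc, ap = cross_validate(X, y, 0.003, seed=0)
        assert auc > 0.75

    def test_permuted_labels_null(self, matrix):
        X, y, *_ = matrix
        y_perm = pd.Series(np.random.default_rng(0).permutation(y.to_numpy()),
                           index=y.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            auc, _ = cross_validate(X, y_perm, 0.003, seed=0)
        assert abs(auc - 0.5) < 0.05

    def test_deterministic(self, matrix):
        X, y, *_ = matrix
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert cross_validate(X, y, 0.01, seed=5) == \
                cross_validate(X, y, 0.01, seed=5)

    def test_too_few_patients_rejected(self, matrix):
        X, y, *_ = matrix
        ids = X.index.get_level_values("patient_id").unique()[:5]
        mask = X.index.get_level_values("patient_id").isin(ids)
        with pytest.raises(ValueError):
            cross_validate(X[mask], y[mask], 0.01)


class TestSelectModel:
    def test_single_candidate_returned(self, default_cohort):
        X, y, meta, mp, patterns = _labeled_matrix(default_cohort)
        cand = {"params": mp, "X": X, "y": y, "patterns": patterns, "meta": meta}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            winner, lam, cv_auc, cv_ap, refit = select_model(
                [cand], lambdas=(0.01,), seed=0)
        assert winner is cand and lam == 0.01
        assert 0 <= cv_auc <= 1 and refit.cv_auc == cv_auc

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_model([])
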