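"""Cross-validated elastic-net classification: splits, transform, metrics, leakage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import skew
from sklearn.metrics import average_precision_score, roc_auc_score

import wearpipe as wp
from wearpipe.classify import FlaggedPowerTransformer, fit_elastic_logistic, make_partitions
from wearpipe.params import PipelineParams


def _brute_auroc(scores, labels):
    """Oracle: double loop over all positive-negative pairs, ties half-credited."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _brute_average_precision(scores, labels):
    """Oracle: explicit precision/recall sweep over descending distinct thresholds."""
    n_pos = sum(labels)
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        tp = sum(1 for s, l in zip(scores, labels) if s >= t and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= t and l == 0)
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def _feature_matrix(n=24, p=10, effect=2.0, seed=0):
    """Small labelled matrix: first two columns carry the class signal."""
    rng = np.random.default_rng(seed)
    y = pd.Series(np.arange(n) % 2, index=[f"u{i:03d}" for i in range(n)])
    X = rng.normal(size=(n, p))
    X[:, 0] += effect * y.to_numpy()
    X[:, 1] -= effect * y.to_numpy()
    return pd.DataFrame(X, index=y.index,
                        columns=[f"f{j}" for j in range(p)]), y


class TestMakePartitions:
    def test_ten_users_five_folds_of_two(self):
        folds = make_partitions([f"u{i}" for i in range(10)], 5, seed=0)
        assert sorted(folds.value_counts()) == [2, 2, 2, 2, 2]

    def test_eleven_users_sizes_differ_by_at_most_one(self):
        folds = make_partitions([f"u{i}" for i in range(11)], 5, seed=0)
        assert sorted(folds.value_counts()) == [2, 2, 2, 2, 3]

    def test_same_seed_same_assignment(self):
        users = [f"u{i}" for i in range(13)]
        pd.testing.assert_series_equal(make_partitions(users, 5, seed=4),
                                       make_partitions(users, 5, seed=4))

    def test_folds_partition_all_users(self):
        users = [f"u{i}" for i in range(17)]
        folds = make_partitions(users, 5, seed=2)
        assert sorted(folds.index) == sorted(users)
        assert set(folds) <= set(range(5))

    def test_too_few_users_fatal(self):
        with pytest.raises(ValueError, match="cannot split"):
            make_partitions(["a", "b"], 5, seed=0)


class TestFlaggedPowerTransformer:
    def test_train_columns_standardized(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(0, 1, size=(200, 3))
        t = FlaggedPowerTransformer().fit(X)
        Z = t.transform(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1, atol=1e-6)

    def test_normal_column_near_identity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, size=(500, 1))
        Z = FlaggedPowerTransformer().fit(X).transform(X)
        # already Gaussian: the fitted transform is close to plain standardization
        ref = (X - X.mean()) / X.std()
        assert np.corrcoef(Z.ravel(), ref.ravel())[0, 1] > 0.999

    def test_lognormal_skewness_reduced(self):
        rng = np.random.default_rng(3)
        X = rng.lognormal(0, 1, size=(500, 1))
        Z = FlaggedPowerTransformer().fit(X).transform(X)
        assert abs(skew(Z.ravel())) < abs(skew(X.ravel()))

    def test_constant_column_passes_through_flagged(self):
        X = np.column_stack([np.full(10, 7.0), np.arange(10.0)])
        t = FlaggedPowerTransformer().fit(X)
        Z = t.transform(X)
        assert list(t.zero_variance_cols_) == [0]
        np.testing.assert_array_equal(Z[:, 0], X[:, 0])

    def test_apply_is_deterministic_no_refit(self):
        rng = np.random.default_rng(4)
        train, test = rng.normal(size=(50, 4)), rng.normal(size=(20, 4))
        t = FlaggedPowerTransformer().fit(train)
        np.testing.assert_array_equal(t.transform(test), t.transform(test.copy()))

    def test_column_mismatch_fatal(self):
        t = FlaggedPowerTransformer().fit(np.random.default_rng(5).normal(size=(10, 3)))
        with pytest.raises(ValueError, match="column mismatch"):
            t.transform(np.zeros((4, 2)))

    def test_empty_matrix_maps_to_empty(self):
        t = FlaggedPowerTransformer().fit(np.random.default_rng(6).normal(size=(10, 3)))
        assert t.transform(np.empty((0, 3))).shape == (0, 3)


class TestFitElasticLogistic:
    def test_separable_toy_finite_with_sign_structure(self):
        X, y = _feature_matrix(n=20, p=2, effect=5.0, seed=7)
        model = fit_elastic_logistic(X.to_numpy(), y.to_numpy(), strength=0.1)
        assert np.isfinite(model.coef_).all()
        assert model.coef_[0, 0] > 0 > model.coef_[0, 1]

    def test_null_labels_give_chance_out_of_sample_auroc(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(200, 5))
        y = rng.integers(0, 2, 200)
        model = fit_elastic_logistic(X[:100], y[:100])
        scores = model.predict_proba(X[100:])[:, 1]
        assert wp.auroc(scores, y[100:]) == pytest.approx(0.5, abs=0.1)

    def test_duplication_equivalent_to_doubling_c(self):
        # penalty is fixed relative to the summed loss, so duplicating every
        # row matches halving the effective regularization (doubling C)
        X, y = _feature_matrix(n=30, p=4, effect=1.0, seed=9)
        Xd = np.vstack([X.to_numpy()] * 2)
        yd = np.concatenate([y.to_numpy()] * 2)
        a = fit_elastic_logistic(Xd, yd, strength=1.0)
        b = fit_elastic_logistic(X.to_numpy(), y.to_numpy(), strength=2.0)
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-4)

    def test_single_class_fatal(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_elastic_logistic(np.zeros((4, 2)), np.ones(4))


class TestMetrics:
    def test_perfect_separation_auroc_one(self):
        assert wp.auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_enumerated_pairs(self):
        # 4 positive-negative pairs, 3 concordant
        assert wp.auroc([0.1, 0.2, 0.3, 0.4], [0, 1, 0, 1]) == 0.75

    def test_all_ties_give_half(self):
        assert wp.auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_auroc_single_class_fatal(self):
        with pytest.raises(ValueError, match="both classes"):
            wp.auroc([0.1, 0.2], [1, 1])

    def test_perfect_ranking_ap_one(self):
        assert wp.average_precision([0.9, 0.1], [1, 0]) == 1.0

    def test_step_sum_hand_computed(self):
        # thresholds 0.9, 0.8, 0.7 -> 0.5*1 + 0.5*(2/3)
        assert wp.average_precision([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(5 / 6)

    def test_all_positives_ap_one(self):
        assert wp.average_precision([0.3, 0.2, 0.1], [1, 1, 1]) == 1.0

    def test_ap_without_positives_fatal(self):
        with pytest.raises(ValueError, match="positives"):
            wp.average_precision([0.1], [0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_metrics_match_oracles_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.choice(rng.normal(size=max(2, n // 2)), n)  # forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert wp.auroc(scores, labels) == pytest.approx(_brute_auroc(scores, labels))
        assert wp.auroc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))
        assert wp.average_precision(scores, labels) == pytest.approx(
            _brute_average_precision(scores, labels))
        assert wp.average_precision(scores, labels) == pytest.approx(
            average_precision_score(labels, scores))


@pytest.fixture(scope="module")
def result():
    X, y = _feature_matrix(n=24, p=10, effect=2.0, seed=0)
    params = PipelineParams(cv_repeats=10, cv_folds=5, rng_seed=5)
    return wp.cross_validate(X, y, params), X, y, params


class TestCrossValidate:
    def test_result_vectors_have_length_repeats(self, result):
        res, _, _, params = result
        assert len(res.auroc) == params.cv_repeats
        assert len(res.average_precision) == params.cv_repeats

    def test_metrics_in_unit_interval(self, result):
        res = result[0]
        assert all(0 <= v <= 1 for v in res.auroc + res.average_precision)

    def test_each_user_scored_once_per_repeat(self, result):
        res, X, _, params = result
        assert res.scores.notna().sum(axis=0).eq(len(X)).all()
        for assignment in res.fold_assignments:
            assert sorted(assignment) == sorted(X.index)

    def test_signal_detected(self, result):
        res = result[0]
        assert np.mean(res.auroc) > 0.8

    def test_full_determinism_given_master_seed(self, result):
        res, X, y, params = result
        redo = wp.cross_validate(X, y, params)
        assert redo.auroc == res.auroc
        assert redo.average_precision == res.average_precision
        pd.testing.assert_frame_equal(redo.scores, res.scores)
        assert redo.coefficients == res.coefficients

    def test_permuted_labels_near_chance(self):
        X, y = _feature_matrix(n=30, p=10, effect=2.0, seed=1)
        y_perm = pd.Series(np.random.default_rng(2).permutation(y.to_numpy()), index=y.index)
        params = PipelineParams(cv_repeats=5, cv_folds=5, rng_seed=6)
        res = wp.cross_validate(X, y_perm, params)
        assert 0.2 <= np.mean(res.auroc) <= 0.8

    def test_no_leakage_under_test_row_mutation(self):
        X, y = _feature_matrix(n=20, p=6, effect=1.5, seed=3)
        params = PipelineParams(cv_repeats=2, cv_folds=4, rng_seed=7)
        res = wp.cross_validate(X, y, params)
        rep_seed = np.random.SeedSequence([params.rng_seed, 0]).generate_state(1)[0]
        folds = make_partitions(list(X.index), params.cv_folds, seed=int(rep_seed))
        test_users = folds.index[folds == 0]
        X_mut = X.copy()
        X_mut.loc[test_users] = 1e6  # arbitrary corruption of held-out rows
        res_mut = wp.cross_validate(X_mut, y, params)
        assert res_mut.coefficients[0][0] == res.coefficients[0][0]

    def test_missing_cells_imputed_from_train_fold(self):
        X, y = _feature_matrix(n=20, p=6, effect=2.0, seed=4)
        X.iloc[3, 2] = np.nan
        X.iloc[[0, 5, 9], 4] = np.nan
        params = PipelineParams(cv_repeats=2, cv_folds=4, rng_seed=8)
        res = wp.cross_validate(X, y, params)
        assert res.scores.notna().all().all()

    def test_unknown_label_fatal(self):
        X, y = _feature_matrix(n=10, p=3)
        y = y.astype(float)
        y.iloc[0] = np.nan
        with pytest.raises(ValueError, match="labels"):
            wp.cross_validate(X, y, PipelineParams(cv_folds=3))

    def test_stratified_flag_balances_folds(self):
        X, y = _feature_matrix(n=20, p=3)
        folds = make_partitions(list(X.index), 5, seed=0, y=y, stratified=True)
        for f in range(5):
            members = y.loc[folds.index[folds == f]]
            assert set(members) == {0, 1}
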