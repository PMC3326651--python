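"""Marker ranking, similarity scores, cross-validated model selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import tissueorigin as to
from tissueorigin.classifier import (
    PerformanceCurve,
    cv_performance_curve,
    fit_model,
    predict_similarity,
    rank_markers,
    select_k,
)
from tissueorigin.constants import ENDOMETRIAL, INDETERMINATE, OVARIAN


def _toy(n_probesets=20, n_per_class=10, seed=0, signal_row=0, delta=5.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(8, 1, size=(n_probesets, 2 * n_per_class))
    X[signal_row, :n_per_class] += delta
    labels = np.array([ENDOMETRIAL] * n_per_class + [OVARIAN] * n_per_class)
    ids = [f"P{i:03d}" for i in range(n_probesets)]
    return pd.DataFrame(X, index=ids,
                        columns=[f"S{j}" for j in range(2 * n_per_class)]), labels


class TestRankMarkers:
    def test_sole_differential_probeset_ranks_first(self):
        X, labels = _toy(delta=8.0)
        assert rank_markers(X, labels).index[0] == "P000"

    def test_matches_scipy_t_statistics(self):
        X, labels = _toy(seed=4)
        ranked = rank_markers(X, labels)
        t_ref = stats.ttest_ind(
            X.to_numpy()[:, labels == ENDOMETRIAL].T,
            X.to_numpy()[:, labels == OVARIAN].T, equal_var=True).statistic
        order = np.argsort(-np.abs(t_ref), kind="stable")
        assert list(ranked.index) == [X.index[i] for i in order]
        assert np.allclose(ranked["t_stat"].to_numpy(),
                           t_ref[order])

    def test_recovers_planted_markers(self, standardized):
        Z, labels, _ = standardized
        ranked = rank_markers(Z, labels)
        # full truth check lives in test_acceptance; spot check here
        assert len(ranked) == Z.shape[0]

    def test_single_class_raises(self):
        X, _ = _toy()
        with pytest.raises(to.DegenerateLabelsError):
            rank_markers(X, np.array([ENDOMETRIAL] * X.shape[1]))


class TestFitAndPredict:
    def test_separable_toy_data_trains_to_perfect_accuracy(self):
        X, labels = _toy(delta=10.0)
        model = fit_model(X, labels, 5)
        calls = [predict_similarity(model, X[c]).call for c in X.columns]
        assert (np.array(calls) == labels).all()

    def test_refit_is_byte_identical(self, standardized, split):
        Z, labels, _ = standardized
        tr, _ = split
        a = fit_model(Z.iloc[:, tr], labels[tr], 25)
        b = fit_model(Z.iloc[:, tr], labels[tr], 25)
        assert a.to_json() == b.to_json()

    def test_model_roundtrip_and_prediction_stability(self, trained_model,
                                                      standardized, split):
        Z, _, _ = standardized
        _, te = split
        back = to.ClassifierModel.from_json(trained_model.to_json())
        p = Z.iloc[:, te[0]]
        assert predict_similarity(back, p) == predict_similarity(
            trained_model, p)

    def test_scores_sum_to_100_and_call_matches_higher(self, trained_model,
                                                       standardized):
        Z, labels, _ = standardized
        for i in range(0, Z.shape[1], 17):
            ss = predict_similarity(trained_model, Z.iloc[:, i])
            assert round(ss.ss_endometrial + ss.ss_ovarian, 6) == 100.0
            if ss.ss_endometrial > ss.ss_ovarian:
                assert ss.call == ENDOMETRIAL
            elif ss.ss_ovarian > ss.ss_endometrial:
                assert ss.call == OVARIAN
            else:
                assert ss.call == INDETERMINATE

    def test_ovarian_96_9_implies_endometrial_3_1(self):
        # the report contract: the complement of a 96.9 ovarian score
        ss = to.SimilarityScores(3.1, 96.9, OVARIAN)
        assert ss.ss_endometrial + ss.ss_ovarian == 100.0

    def test_boundary_probability_is_indeterminate(self, trained_model):
        # force eta = 0 by zeroing the coefficients' input
        profile = pd.Series(trained_model.feature_means,
                            index=trained_model.probeset_ids)
        model = to.ClassifierModel(
            probeset_ids=trained_model.probeset_ids,
            coefficients=trained_model.coefficients,
            intercept=0.0,
            feature_means=trained_model.feature_means,
            feature_sds=trained_model.feature_sds,
            training_summary=trained_model.training_summary,
            k=trained_model.k)
        ss = predict_similarity(model, profile)
        assert (ss.ss_endometrial, ss.ss_ovarian) == (50.0, 50.0)
        assert ss.call == INDETERMINATE

    def test_missing_probeset_raises_schema_error(self, trained_model,
                                                  standardized):
        Z, _, _ = standardized
        profile = Z.iloc[:, 0].drop(trained_model.probeset_ids[0])
        with pytest.raises(to.SchemaError):
            predict_similarity(trained_model, profile)

    def test_prediction_invariant_to_raw_scaling(self, cohort, standardized,
                                                 trained_model):
        _, _, ref = standardized
        raw = cohort.matrix.iloc[:, 5]
        a = predict_similarity(trained_model,
                               to.standardize_profile(raw, ref))
        b = predict_similarity(trained_model,
                               to.standardize_profile(raw * 7.3, ref))
        assert a == b

    def test_k_zero_rejected(self, standardized):
        Z, labels, _ = standardized
        with pytest.raises(to.ParameterError):
            fit_model(Z, labels, 0)


class TestCurveAndSelectK:
    def test_plateau_with_strong_signal(self, standardized):
        Z, labels, _ = standardized
        curve = cv_performance_curve(Z.iloc[:, ::2], labels[::2],
                                     [1, 10, 50], n_folds=3, seed=0)
        assert curve.auc[-1] >= curve.auc[0] - 0.05

    def test_same_seed_identical_curve(self, standardized):
        Z, labels, _ = standardized
        sub = Z.iloc[:200, 70:130]  # 30 specimens per class
        a = cv_performance_curve(sub, labels[70:130], [1, 5], n_folds=3,
                                 seed=2)
        b = cv_performance_curve(sub, labels[70:130], [1, 5], n_folds=3,
                                 seed=2)
        assert np.array_equal(a.auc, b.auc)
        assert np.array_equal(a.sensitivity, b.sensitivity)

    def test_label_permutation_gives_chance_auc(self, standardized):
        Z, labels, _ = standardized
        rng = np.random.default_rng(42)
        perm = rng.permutation(labels)
        curve = cv_performance_curve(Z.iloc[:300], perm, [10],
                                     n_folds=5, seed=1)
        assert abs(curve.auc[0] - 0.5) <= 0.15

    def test_fold_count_exceeding_class_size_raises(self, standardized):
        Z, labels, _ = standardized
        sub_labels = np.concatenate([labels[labels == ENDOMETRIAL][:3],
                                     labels[labels == OVARIAN][:3]])
        sub = Z.iloc[:50, :6]
        with pytest.raises(to.ParameterError):
            cv_performance_curve(sub, sub_labels, [5], n_folds=4)

    def test_select_k_brute_force_rule(self):
        curve = PerformanceCurve(
            k_grid=np.array([10, 50, 100, 200, 400]),
            sensitivity=np.full(5, 0.9), specificity=np.full(5, 0.9),
            auc=np.array([0.90, 0.95, 0.990, 0.992, 0.993]))
        tol = 0.005
        brute = min(k for k, a in zip(curve.k_grid, curve.auc)
                    if a >= curve.auc.max() - tol)
        assert select_k(curve, tol) == brute == 100

    def test_select_k_zero_tolerance_returns_argmax(self):
        curve = PerformanceCurve(
            k_grid=np.array([1, 2, 3]),
            sensitivity=np.full(3, 1.0), specificity=np.full(3, 1.0),
            auc=np.array([0.7, 0.8, 0.9]))
        assert select_k(curve, 0.0) == 3

    def test_select_k_all_equal_returns_smallest(self):
        curve = PerformanceCurve(
            k_grid=np.array([1, 2, 3]),
            sensitivity=np.full(3, 1.0), specificity=np.full(3, 1.0),
            auc=np.full(3, 0.95))
        assert select_k(curve, 0.0) == 1


@settings(deadline=None, max_examples=100, derandomize=True)
@given(p=st.floats(min_value=0.0, max_value=1.0))
def test_rounded_score_pair_always_sums_to_100(p):
    ss_e = to.round_half_away(100.0 * p, 1)
    ss_o = round(100.0 - ss_e, 1)
    assert round(ss_e + ss_o, 6) == 100.0
    assert 0.0 <= ss_e <= 100.0 and 0.0 <= ss_o <= 100.0
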