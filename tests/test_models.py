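"""Single-model algorithms, TSS/ROC evaluation and ensembles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from hpvsdm import (ALGORITHMS, AlgorithmSpec, EmptyEnsembleError,
                    ENSEMBLE_METHODS, ModelMatrix, ModelResult,
                    build_ensemble, classify_tss_quality, cross_validate,
                    evaluate_roc, evaluate_tss, fit_algorithm, fit_sre)
from hpvsdm.models import EnsembleModel, FittedModel, TSS_THRESHOLDS


def toy_matrix(n=300, p=4, seed=0, separable=False):
    """Random predictors; response from a logistic signal (or separable)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if separable:
        y = (X[:, 0] > 0).astype(int)
    else:
        prob = 1 / (1 + np.exp(-(1.5 * X[:, 0] - X[:, 1])))
        y = (rng.random(n) < prob).astype(int)
    df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
    df["response"] = y
    df["provenance"] = np.where(y == 1, "presence", "pseudoabsence")
    return ModelMatrix(df, [f"x{j}" for j in range(p)])


class TestEvaluateTss:
    def test_worked_confusion_matrix_arithmetic(self):
        # at any threshold in (0.2, 0.8]: TP=40 FN=10 TN=45 FP=5
        # sensitivity 0.8 + specificity 0.9 - 1 = 0.7, and no threshold
        # does better
        scores = np.concatenate([np.full(40, 0.8), np.full(10, 0.2),
                                 np.full(45, 0.2), np.full(5, 0.8)])
        labels = np.concatenate([np.ones(50), np.zeros(50)]).astype(int)
        tss, thr = evaluate_tss(scores, labels)
        assert tss == pytest.approx(0.8 + 0.9 - 1.0, abs=1e-12)

    def test_perfect_scores_reach_one(self):
        labels = np.array([0, 1, 0, 1, 1, 0])
        tss, _ = evaluate_tss(labels.astype(float), labels)
        assert tss == pytest.approx(1.0)

    def test_matches_exhaustive_scan_oracle(self, rng):
        for _ in range(20):
            n = 200
            scores = rng.random(n)
            labels = (rng.random(n) < 0.4).astype(int)
            tss, thr = evaluate_tss(scores, labels)
            # independent exhaustive scan
            best, best_t = -np.inf, None
            pos = labels == 1
            for t in TSS_THRESHOLDS:
                pred = scores >= t
                sens = (pred & pos).sum() / pos.sum()
                spec = (~pred & ~pos).sum() / (~pos).sum()
                if sens + spec - 1 > best:
                    best, best_t = sens + spec - 1, t
            assert tss == pytest.approx(best, abs=1e-12)
            assert thr == pytest.approx(best_t, abs=1e-12)

    def test_random_scores_give_small_tss(self, rng):
        scores = rng.random(2000)
        labels = (rng.random(2000) < 0.5).astype(int)
        tss, _ = evaluate_tss(scores, labels)
        assert abs(tss) < 0.15

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            evaluate_tss(np.array([0.5, 0.6]), np.array([1, 1]))


class TestEvaluateRoc:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        assert evaluate_roc(np.array([0.1, 0.2, 0.8, 0.9]), labels) == 1.0

    def test_inverted_scores(self):
        labels = np.array([0, 0, 1, 1])
        assert evaluate_roc(np.array([0.9, 0.8, 0.2, 0.1]), labels) == 0.0

    def test_matches_curve_based_oracle(self, rng):
        for _ in range(100):
            n = 80
            scores = rng.random(n).round(2)  # rounded to force ties
            labels = (rng.random(n) < 0.5).astype(int)
            if labels.min() == labels.max():
                continue
            assert evaluate_roc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)


class TestClassifyTssQuality:
    @pytest.mark.parametrize("tss,expected", [
        (0.38, "moderate or below"),
        (0.4, "good"), (0.6, "good"),
        (0.65, "very good"),
        (0.7, "ensemble-eligible"), (0.82, "ensemble-eligible"),
    ])
    def test_categories(self, tss, expected):
        assert classify_tss_quality(tss) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_tss_quality(1.5)


class TestSre:
    def test_alpha_zero_covers_every_training_presence(self, rng):
        X = rng.standard_normal((40, 3))
        model = fit_sre(X, alpha=0.0)
        assert (model(X) == 1.0).all()

    def test_case_outside_one_envelope_is_rejected(self, rng):
        X = rng.uniform(0, 1, (30, 2))
        model = fit_sre(X, alpha=0.0)
        assert model(np.array([[0.5, 5.0]]))[0] == 0.0

    def test_inside_fraction_matches_quantile_oracle(self, rng):
        X = rng.standard_normal((50, 3))
        alpha = 0.1
        model = fit_sre(X, alpha=alpha)
        predicted = model(X)
        lo = np.quantile(X, alpha, axis=0)
        hi = np.quantile(X, 1 - alpha, axis=0)
        brute = ((X >= lo) & (X <= hi)).all(axis=1).astype(float)
        np.testing.assert_array_equal(predicted, brute)

    def test_prediction_is_binary(self, rng):
        X = rng.standard_normal((30, 2))
        out = fit_sre(X)(rng.standard_normal((100, 2)))
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError):
            fit_sre(np.ones((1, 2)))


class TestFitAlgorithm:
    @pytest.mark.parametrize("name", ALGORITHMS)
    def test_separable_data_reaches_tss_one_on_training(self, name):
        matrix = toy_matrix(n=200, separable=True, seed=1)
        hp = (("alpha", 0.0),) if name == "SRE" else ()
        fitted = fit_algorithm(AlgorithmSpec(name, hp, seed=0),
                               matrix.X, matrix.y)
        tss, _ = evaluate_tss(fitted(matrix.X), matrix.y)
        assert tss == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("name", ALGORITHMS)
    def test_scores_bounded_in_unit_interval(self, name, rng):
        matrix = toy_matrix(n=150, seed=2)
        fitted = fit_algorithm(AlgorithmSpec(name, seed=0),
                               matrix.X, matrix.y)
        scores = fitted(rng.standard_normal((1000, 4)) * 3)
        assert (scores >= 0).all() and (scores <= 1).all()

    @pytest.mark.parametrize("name", ("RF", "GBM", "ANN"))
    def test_stochastic_learners_deterministic_given_seed(self, name):
        matrix = toy_matrix(n=150, seed=3)
        Xnew = np.random.default_rng(0).standard_normal((50, 4))
        a = fit_algorithm(AlgorithmSpec(name, seed=11), matrix.X, matrix.y)
        b = fit_algorithm(AlgorithmSpec(name, seed=11), matrix.X, matrix.y)
        np.testing.assert_array_equal(a(Xnew), b(Xnew))

    def test_single_class_input_rejected(self):
        X = np.random.default_rng(0).standard_normal((30, 2))
        with pytest.raises(ValueError):
            fit_algorithm(AlgorithmSpec("RF"), X, np.ones(30, dtype=int))

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            AlgorithmSpec("GLM")


class TestCrossValidate:
    def test_result_count_and_grouping(self):
        matrix = toy_matrix(n=250, seed=4)
        cv = cross_validate("v", matrix, ALGORITHMS, n_repetitions=3, seed=0)
        results = cv.results
        assert len(results) == 7 * 3
        assert all(r.group == "single" for r in results)
        assert {r.algorithm for r in results} == set(ALGORITHMS)

    def test_deterministic_given_seed(self):
        matrix = toy_matrix(n=200, seed=5)
        cv1 = cross_validate("v", matrix, ("RF", "SRE"), seed=42)
        cv2 = cross_validate("v", matrix, ("RF", "SRE"), seed=42)
        assert cv1.results == cv2.results

    def test_bad_eval_fraction_rejected(self):
        with pytest.raises(ValueError):
            cross_validate("v", toy_matrix(), eval_fraction=0.9)


def _member(scores_value, tss, threshold=0.5):
    """A constant-scorer member with a pinned evaluation result."""
    fitted = FittedModel(AlgorithmSpec("RF"),
                         lambda X, v=scores_value: np.full(len(X), v))
    fitted.result = ModelResult("v", "RF", 0, 0, "single", tss, 0.9,
                                threshold)
    return fitted


class TestEnsembles:
    def test_single_member_reproduced_by_all_point_methods(self):
        m = _member(0.63, 0.8)
        X = np.zeros((10, 2))
        for method in ("mean", "weighted_mean", "median", "ci_inf", "ci_sup"):
            out = EnsembleModel(method, [m])(X)
            np.testing.assert_allclose(out, 0.63)

    def test_mean_and_median_arithmetic(self):
        members = [_member(v, 0.75) for v in (0.2, 0.4, 0.9)]
        X = np.zeros((5, 2))
        np.testing.assert_allclose(EnsembleModel("mean", members)(X), 0.5)
        np.testing.assert_allclose(EnsembleModel("median", members)(X), 0.4)

    def test_weighted_mean_matches_hand_computation(self):
        members = [_member(0.2, 0.35), _member(0.4, 0.35), _member(0.9, 0.7)]
        # weights proportional to TSS: (0.25, 0.25, 0.5)
        expected = 0.25 * 0.2 + 0.25 * 0.4 + 0.5 * 0.9
        out = EnsembleModel("weighted_mean", members)(np.zeros((10, 2)))
        np.testing.assert_allclose(out, expected)

    def test_committee_averaging_binarizes_at_member_thresholds(self):
        members = [_member(0.6, 0.8, threshold=0.5),
                   _member(0.6, 0.8, threshold=0.7)]
        out = EnsembleModel("committee_avg", members)(np.zeros((4, 2)))
        np.testing.assert_allclose(out, 0.5)  # one vote of two

    def test_bounds_and_ci_ordering(self, rng):
        members = []
        for v in (0.1, 0.5, 0.8):
            members.append(_member(v, 0.9))
        X = np.zeros((7, 2))
        S = np.array([0.1, 0.5, 0.8])
        mean = EnsembleModel("mean", members)(X)
        lo = EnsembleModel("ci_inf", members)(X)
        hi = EnsembleModel("ci_sup", members)(X)
        med = EnsembleModel("median", members)(X)
        for arr in (mean, med):
            assert (arr >= S.min() - 1e-12).all()
            assert (arr <= S.max() + 1e-12).all()
        assert (lo <= mean + 1e-12).all()
        assert (mean <= hi + 1e-12).all()

    def test_gate_filters_members_and_empty_gate_raises(self):
        matrix = toy_matrix(n=300, separable=True, seed=6)
        cv = cross_validate("v", matrix, ("RF", "GBM"), n_repetitions=2,
                            seed=0)
        results, ensembles = build_ensemble(cv, gate=0.7)
        assert results
        assert all(r.group == "ensemble" for r in results)
        assert {r.ensemble_method for r in results} <= set(ENSEMBLE_METHODS)
        with pytest.raises(EmptyEnsembleError, match="1.01"):
            build_ensemble(cv, gate=1.01)

    def test_ensemble_evaluated_on_held_out_cases(self):
        matrix = toy_matrix(n=400, seed=7)
        cv = cross_validate("v", matrix, ("RF",), n_repetitions=1, seed=0,
                            eval_fraction=0.25)
        results, ensembles = build_ensemble(cv, gate=-1.0)
        # a one-member mean ensemble must match its member's evaluation
        single = cv.results[0]
        ens_mean = [r for r in results if r.ensemble_method == "mean"][0]
        assert ens_mean.tss == pytest.approx(single.tss)
        assert ens_mean.roc_auc == pytest.approx(single.roc_auc)
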