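"""Class-weighted L1 SVM: LP optimality, penalties, scoring, classification."""

import numpy as np
import pandas as pd
import pytest

from sepsipanel import (AlignmentError, DegenerateDataError, GeneratorConfig,
                        class_penalties, classify, decision_score, fit_l1_svm,
                        normalize, sample_cohort)
from sepsipanel.preprocess import NormalizationParams

from .oracles import epigraph_l1_svm_objective


def separable_instance(seed=11, n=40, p=5, gap=2.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, p))
    X[:, 0] += gap * (2 * y - 1)
    return X, y


class TestClassPenalties:
    def test_minority_positive_upweighted(self):
        y = np.array([0] * 20 + [1] * 10)
        assert class_penalties(y) == (2.0, 1.0)

    def test_balanced_classes(self):
        y = np.array([0, 1] * 10)
        assert class_penalties(y) == (1.0, 1.0)

    def test_swapped_convention(self):
        y = np.array([0] * 10 + [1] * 20)
        assert class_penalties(y, positive_upweighted=False) == (1.0, 2.0)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            class_penalties(np.ones(5))


class TestFitL1Svm:
    def test_two_point_instance_solved_exactly(self):
        # one point per class at -1/+1: optimum w=1, b=0, no slack, |obj|=1
        X = np.array([[-1.0], [1.0]])
        y = np.array([0, 1])
        model, diag = fit_l1_svm(X, y, penalties=(1.0, 1.0))
        assert diag.slacks.max() < 1e-8
        assert abs(model.weights[0]) <= 1 + 1e-6
        scores = X[:, 0] * model.weights[0] + model.bias
        assert np.all(np.sign(scores) == [-1, 1])
        # margin constraints active at the optimum
        np.testing.assert_allclose(np.abs(scores), 1.0, atol=1e-8)
        assert diag.objective_value == pytest.approx(
            epigraph_l1_svm_objective(X, y, 1.0, 1.0), abs=1e-6)

    def test_zero_column_gets_zero_weight(self):
        X, y = separable_instance()
        X[:, 3] = 0.0
        model, _ = fit_l1_svm(X, y)
        assert model.weights[3] == 0.0

    def test_separable_instance_zero_training_error(self):
        X, y = separable_instance(seed=11)
        model, diag = fit_l1_svm(X, y, penalties=(1.0, 1.0))
        preds = classify(X @ model.weights + model.bias)
        assert np.array_equal(preds, y)
        assert diag.objective_value == pytest.approx(
            epigraph_l1_svm_objective(X, y, 1.0, 1.0), abs=1e-6)

    def test_objective_identity(self):
        X, y = separable_instance(seed=4, gap=0.5)
        penalties = class_penalties(y)
        model, diag = fit_l1_svm(X, y, penalties=penalties)
        c_pos, c_neg = penalties
        cost = np.where(y == 1, c_pos, c_neg)
        recomputed = np.abs(model.weights).sum() + float(cost @ diag.slacks)
        assert recomputed == pytest.approx(diag.objective_value, abs=1e-6)

    def test_objective_beats_random_feasible_candidates(self):
        X, y = separable_instance(seed=9, n=24, p=3, gap=0.8)
        y_pm = 2 * y - 1.0
        model, diag = fit_l1_svm(X, y, penalties=(1.0, 1.0))
        rng = np.random.default_rng(0)
        for _ in range(100):
            w = rng.normal(size=3)
            b = rng.normal()
            xi = np.clip(1 - y_pm * (X @ w + b), 0, None)
            candidate = np.abs(w).sum() + xi.sum()
            assert diag.objective_value <= candidate + 1e-8

    def test_sparsity_monotone_in_penalty(self):
        X, y = separable_instance(seed=2, n=60, p=8, gap=0.7)
        _, diag_hi = fit_l1_svm(X, y, penalties=(1.0, 1.0))
        _, diag_lo = fit_l1_svm(X, y, penalties=(0.1, 0.1))
        assert diag_lo.n_nonzero_weights <= diag_hi.n_nonzero_weights

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_l1_svm(np.ones((4, 2)), np.ones(4))


class TestDecisionScore:
    def test_input_at_means_scores_zero(self):
        from sepsipanel import load_published_model
        model = load_published_model()
        assert decision_score(model.norm_params.mean, model) == pytest.approx(0.0)

    def test_dataframe_alignment_by_name(self):
        from sepsipanel import load_published_model
        model = load_published_model()
        df = pd.DataFrame([{"HCO3": 27.270, "Ang-1": 2649.2, "Ang-2": 8518.1}])
        np.testing.assert_allclose(decision_score(df, model), [0.0], atol=1e-12)
        with pytest.raises(AlignmentError):
            decision_score(df.drop(columns=["HCO3"]), model)

    def test_vector_length_checked(self):
        from sepsipanel import load_published_model
        with pytest.raises(AlignmentError):
            decision_score(np.zeros(4), load_published_model())


class TestClassify:
    @pytest.mark.parametrize("score,expected", [
        (0.0, 1), (-1e-12, 0), (2.7, 1), (-0.3, 0),
    ])
    def test_boundary_rule(self, score, expected):
        assert classify(score) == expected

    def test_vectorized(self):
        np.testing.assert_array_equal(classify(np.array([-1.0, 0.0, 1.0])),
                                      [0, 1, 1])


class TestPlantedWeightSigns:
    @pytest.mark.parametrize("seed", [101, 102, 103])
    def test_panel_weight_directions(self, seed):
        cohort = sample_cohort(GeneratorConfig(seed=seed, dropout_prob=0.0))
        X = cohort.features().loc[:, ["Ang-2", "Ang-1", "HCO3"]]
        Xn, params = normalize(X)
        y = cohort.labels()
        model, _ = fit_l1_svm(Xn, y, penalties=class_penalties(y),
                              norm_params=params)
        w = dict(zip(model.feature_names, model.weights))
        assert w["Ang-2"] > 0
        assert w["Ang-1"] < 0
        assert w["HCO3"] < 0


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path):
        X, y = separable_instance()
        Xn, params = normalize(pd.DataFrame(X, columns=[f"b{j}" for j in range(5)]))
        model, _ = fit_l1_svm(Xn, y, norm_params=params)
        path = tmp_path / "model.json"
        model.to_json(path, provenance="test")
        from sepsipanel import LinearModel
        back = LinearModel.from_json(path)
        np.testing.assert_allclose(back.weights, model.weights)
        assert back.bias == pytest.approx(model.bias)
        assert back.feature_names == model.feature_names
        np.testing.assert_allclose(back.norm_params.sd, model.norm_params.sd)


def test_identity_norm_params_for_prenormalized_fit():
    X, y = separable_instance()
    model, _ = fit_l1_svm(X, y)
    assert isinstance(model.norm_params, NormalizationParams)
    np.testing.assert_allclose(model.norm_params.mean, 0.0)
    np.testing.assert_allclose(model.norm_params.sd, 1.0)
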