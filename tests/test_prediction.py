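"""Nested-selection LOOCV, the linear classifier, and the permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctcpredict.datatypes import ExpressionMatrix, GOOD, POOR
from ctcpredict.prediction import (
    NoInformativeGenesError,
    apply_predictor,
    finalize_predictor,
    gene_stats,
    loocv,
    permutation_test,
    select_genes,
    train_linear_svm,
    two_sample_t,
)


def _expr_labels(X: np.ndarray, y: list[str]):
    expr = ExpressionMatrix(
        pd.DataFrame(
            X,
            index=[f"G{i}" for i in range(X.shape[0])],
            columns=[f"P{j}" for j in range(X.shape[1])],
        )
    )
    labels = pd.Series(y, index=expr.samples)
    return expr, labels


@pytest.fixture(scope="module")
def random_expr():
    rng = np.random.default_rng(42)
    X = rng.normal(size=(25, 16))
    y = [GOOD] * 9 + [POOR] * 7
    return _expr_labels(X, y)


def test_t_statistic_matches_scipy_oracle(random_expr):
    expr, labels = random_expr
    st = gene_stats(expr, labels)
    good = expr.delta_ct.loc[:, (labels == GOOD).values]
    poor = expr.delta_ct.loc[:, (labels == POOR).values]
    t_ref, p_ref = stats.ttest_ind(good, poor, axis=1, equal_var=True)
    np.testing.assert_allclose(st["t_value"].to_numpy(), t_ref, rtol=1e-10)
    np.testing.assert_allclose(st["p_value"].to_numpy(), p_ref, rtol=1e-10)


def test_identical_groups_give_t_zero_p_one():
    expr, labels = _expr_labels(
        np.array([[1.0, 1, 1, 1], [2.0, 2, 2, 2]]), [GOOD, GOOD, POOR, POOR]
    )
    gs = two_sample_t(expr, labels, "G0")
    assert gs.t_value == 0.0
    assert gs.p_value == 1.0


def test_separated_groups_give_large_t_small_p():
    rng = np.random.default_rng(0)
    X = np.concatenate(
        [np.zeros((1, 4)), np.ones((1, 4))], axis=1
    ) + rng.normal(0, 1e-3, (1, 8))
    expr, labels = _expr_labels(X, [GOOD] * 4 + [POOR] * 4)
    gs = two_sample_t(expr, labels, "G0")
    assert abs(gs.t_value) > 100
    assert gs.p_value < 1e-3


def test_label_swap_negates_t_keeps_p(random_expr):
    expr, labels = random_expr
    swapped = labels.map({GOOD: POOR, POOR: GOOD})
    a = gene_stats(expr, labels)
    b = gene_stats(expr, swapped)
    np.testing.assert_allclose(a["t_value"].to_numpy(), -b["t_value"].to_numpy())
    np.testing.assert_allclose(a["p_value"].to_numpy(), b["p_value"].to_numpy())


def test_sign_convention_positive_means_higher_in_good():
    X = np.array([[5.0, 5, 5, 0.0, 0, 0]])  # higher expression in good
    expr, labels = _expr_labels(X + np.arange(6) * 1e-4, [GOOD] * 3 + [POOR] * 3)
    assert two_sample_t(expr, labels, "G0").t_value > 0


def test_select_genes_alpha_one_returns_all_ordered_by_p(random_expr):
    expr, labels = random_expr
    sel = select_genes(expr, labels, alpha=1.0)
    assert set(sel) == set(expr.genes)
    st = gene_stats(expr, labels)
    ps = [st.loc[g, "p_value"] for g in sel]
    assert ps == sorted(ps)


def test_select_genes_null_rate_near_alpha():
    rng = np.random.default_rng(5)
    rates = []
    for _ in range(60):
        X = rng.normal(size=(93, 45))
        expr, labels = _expr_labels(X, [GOOD] * 26 + [POOR] * 19)
        rates.append(len(select_genes(expr, labels, alpha=0.1)) / 93)
    assert np.mean(rates) == pytest.approx(0.1, abs=0.03)


def test_svm_separable_threshold_between_clusters():
    X = np.array([[0.0, 0.2, 0.1, 4.0, 4.2, 3.9]])
    expr, labels = _expr_labels(X, [GOOD] * 3 + [POOR] * 3)
    model = train_linear_svm(expr, labels, ["G0"])
    calls = model.predict(expr)
    assert (calls == labels).all()  # zero training errors
    # decision boundary sits between the cluster means
    boundary = model.center[0] - model.intercept * model.scale[0] / model.weights[0]
    assert 0.2 < boundary < 3.9


def test_model_serialization_roundtrip(tmp_path, planted_cohort):
    _, expr, labels = planted_cohort
    model = finalize_predictor(expr, labels)
    model.save(tmp_path / "model.json")
    from ctcpredict.datatypes import PredictorModel

    back = PredictorModel.load(tmp_path / "model.json")
    pd.testing.assert_series_equal(back.predict(expr), model.predict(expr))
    np.testing.assert_allclose(back.weights, model.weights)


def test_loocv_nested_selection_ignores_held_out_sample(planted_cohort):
    """Perturbing the held-out sample must not change that fold's genes."""
    _, expr, labels = planted_cohort
    cv = loocv(expr, labels)
    perturbed = expr.delta_ct.copy()
    perturbed.iloc[:, 0] += 100.0  # wreck sample 0 only
    cv2 = loocv(ExpressionMatrix(perturbed), labels)
    assert cv.fold_genes[0] == cv2.fold_genes[0]


def test_loocv_error_low_on_planted_cohort(planted_cohort):
    _, expr, labels = planted_cohort
    cv = loocv(expr, labels)
    assert cv.error < 0.25
    assert cv.error == np.mean(cv.predictions != labels)
    assert len(cv.fold_genes) == len(labels)


def test_loocv_refuses_tiny_or_imbalanced_input():
    rng = np.random.default_rng(1)
    expr, labels = _expr_labels(rng.normal(size=(5, 8)), [GOOD] * 4 + [POOR] * 4)
    with pytest.raises(ValueError, match="n >= 10"):
        loocv(expr, labels)
    expr, labels = _expr_labels(rng.normal(size=(5, 12)), [GOOD] * 10 + [POOR] * 2)
    with pytest.raises(ValueError):
        loocv(expr, labels)


def test_empty_fold_selection_predicts_majority_class():
    rng = np.random.default_rng(2)
    expr, labels = _expr_labels(rng.normal(size=(6, 12)), [GOOD] * 8 + [POOR] * 4)
    cv = loocv(expr, labels, alpha=1e-12)  # nothing can be selected
    assert all(len(g) == 0 for g in cv.fold_genes)
    assert (cv.predictions == GOOD).all()


def test_permutation_p_bounds_and_determinism(planted_cohort):
    _, expr, labels = planted_cohort
    cv1 = permutation_test(expr, labels, n_permutations=20, seed=3)
    cv2 = permutation_test(expr, labels, n_permutations=20, seed=3)
    assert cv1.permutation_p == cv2.permutation_p
    assert 1 / 21 <= cv1.permutation_p <= 1.0
    with pytest.raises(ValueError):
        permutation_test(expr, labels, n_permutations=0, seed=3)


def test_finalize_predictor_recovers_planted_genes(planted_cohort):
    cohort, expr, labels = planted_cohort
    model = finalize_predictor(expr, labels)
    planted = set(cohort.truth_informative_genes)
    assert len(planted & set(model.genes)) >= 6
    # every reported gene reached the selection threshold
    assert set(model.genes) == set(select_genes(expr, labels, alpha=0.1))


def test_finalize_predictor_alpha_zero_raises(planted_cohort):
    _, expr, labels = planted_cohort
    with pytest.raises(NoInformativeGenesError):
        finalize_predictor(expr, labels, alpha=1e-300)


def test_apply_predictor_reproduces_training_calls(planted_cohort):
    _, expr, labels = planted_cohort
    model = finalize_predictor(expr, labels)
    calls = apply_predictor(model, expr)
    assert (calls == model.predict(expr)).all()
    training_error = np.mean(calls != labels)
    assert training_error <= loocv(expr, labels).error + 1e-12


def test_apply_predictor_missing_gene_errors(planted_cohort):
    _, expr, labels = planted_cohort
    model = finalize_predictor(expr, labels)
    reduced = expr.subset_genes([g for g in expr.genes if g != model.genes[0]])
    with pytest.raises(ValueError, match=model.genes[0]):
        apply_predictor(model, reduced)


def test_constant_shift_moves_decision_scores_predictably(planted_cohort):
    """Adding +c to all delta-Ct shifts each score by c * sum(w/scale)."""
    _, expr, labels = planted_cohort
    model = finalize_predictor(expr, labels)
    c = 1.7
    shifted = ExpressionMatrix(expr.delta_ct + c)
    d0 = model.decision(expr)
    d1 = model.decision(shifted)
    expected = c * float(np.sum(model.weights / model.scale))
    np.testing.assert_allclose((d1 - d0).to_numpy(), expected, rtol=1e-8)
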