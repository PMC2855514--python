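import numpy as np
import pandas as pd
import pytest

from progsig import (
    ExpressionMatrix,
    ModelSpec,
    deserialize_model,
    encode_clinical,
    generate_cohort,
    make_plugin_model,
    score,
    serialize_model,
    train_dlda,
    train_knn,
    train_logistic,
    train_ntp,
)
from progsig.evaluate import auc
from progsig.models import ScoringError, TrainingError

from conftest import small_config


def expr_1d(values, sample_prefix="S"):
    return ExpressionMatrix(pd.DataFrame(
        [values], index=["G1"],
        columns=[f"{sample_prefix}{i}" for i in range(len(values))],
    ))


def expr_from(array, genes=None):
    array = np.atleast_2d(np.asarray(array, dtype=float))
    return ExpressionMatrix(pd.DataFrame(
        array,
        index=genes or [f"G{i}" for i in range(array.shape[0])],
        columns=[f"S{j}" for j in range(array.shape[1])],
    ))


# ---------------------------------------------------------------------------
# DLDA

_H = np.sqrt(2) / 2  # two points +-h around the mean give unit sample variance


def test_dlda_score_hand_value():
    # class means 0 (indolent) and 2 (lethal), pooled variance 1:
    # score(1.5) = (1.5-0)^2 - (1.5-2)^2 = 2.25 - 0.25 = 2.0
    train = expr_1d([-_H, _H, 2 - _H, 2 + _H])
    labels = ["indolent", "indolent", "lethal", "lethal"]
    model = train_dlda(train, labels)
    s = score(model, expr_1d([1.5], "T"))
    assert s[0] == pytest.approx(2.0)


def test_dlda_midpoint_scores_zero_and_class_mean_positive():
    train = expr_1d([-1, 1, 1, 3])
    labels = ["indolent", "indolent", "lethal", "lethal"]
    model = train_dlda(train, labels)
    assert score(model, expr_1d([1.0], "T"))[0] == pytest.approx(0.0)
    assert score(model, expr_1d([2.0], "T"))[0] > 0


def test_dlda_training_contract():
    with pytest.raises(TrainingError):
        train_dlda(expr_1d([1, 2, 3]), ["lethal", "lethal", "lethal"])


# ---------------------------------------------------------------------------
# kNN

def test_knn_identity_exemplar():
    train = expr_1d([0.0, 5.0])
    model = train_knn(train, ["lethal", "indolent"], k=1)
    assert score(model, expr_1d([0.0], "T"))[0] == 1.0


def test_knn_hand_neighbourhood():
    train = expr_1d([0.0, 1.0, 10.0])
    model = train_knn(train, ["lethal", "lethal", "indolent"], k=3)
    assert score(model, expr_1d([0.4], "T"))[0] == pytest.approx(2 / 3)


def test_knn_tie_break_prefers_lower_index():
    # all exemplars equidistant from the test point: 3 lowest-index win
    train = expr_from([[1, 1, 1, 1], [1, -1, 1, -1]])
    labels = ["lethal", "lethal", "indolent", "indolent"]
    model = train_knn(train, labels, k=3)
    test = expr_from([[1], [0]], genes=["G0", "G1"])
    test.values.columns = ["T0"]
    assert score(model, test)[0] == pytest.approx(2 / 3)


def test_knn_even_k_rejected():
    with pytest.raises(ValueError, match="odd"):
        train_knn(expr_1d([0, 1]), ["lethal", "indolent"], k=2)


def test_knn_k_equal_n_returns_prevalence():
    train = expr_1d([0, 1, 2, 3, 10])
    labels = ["lethal", "lethal", "lethal", "indolent", "indolent"]
    model = train_knn(train, labels, k=5)
    s = score(model, expr_1d([0.0, 100.0], "T"))
    np.testing.assert_allclose(s, 3 / 5)


# ---------------------------------------------------------------------------
# NTP

def test_ntp_cosine_hand_value():
    template = np.array([1.0, 1.0, -1.0])
    sample = np.array([1.0, -1.0, 1.0])
    cos = (template @ sample) / (np.linalg.norm(template) * np.linalg.norm(sample))
    assert cos == pytest.approx(-1 / 3)
    assert 1 - cos == pytest.approx(4 / 3)


def test_ntp_colinear_sample_gets_maximal_score():
    rng = np.random.default_rng(0)
    train = expr_from(rng.normal(0, 1, (3, 8)) + np.outer([1, 1, -1], [2] * 4 + [-2] * 4))
    labels = ["lethal"] * 4 + ["indolent"] * 4
    model = train_ntp(train, labels)
    template = model.params["template"]
    mean, sd = model.params["mean"], model.params["sd"]
    aligned = expr_from((mean + 3 * sd * template)[:, None])
    aligned.values.columns = ["T0"]
    opposite = expr_from((mean - 3 * sd * template)[:, None])
    opposite.values.columns = ["T0"]
    s_aligned = score(model, aligned)[0]
    s_opposite = score(model, opposite)[0]
    assert s_aligned == pytest.approx(2.0)  # cosine distance 0 vs 2
    assert s_opposite == pytest.approx(-2.0)


def test_ntp_degenerate_templates_rejected():
    train = expr_from([[1, 1, 1, 1], [2, 2, 2, 2]])
    with pytest.raises(TrainingError, match="degenerate"):
        train_ntp(train, ["lethal", "lethal", "indolent", "indolent"])


# ---------------------------------------------------------------------------
# logistic

def test_logistic_closed_form_2x2():
    x = pd.DataFrame({"x": [1] * 30 + [0] * 30})
    y = ["lethal"] * 20 + ["indolent"] * 10 + ["lethal"] * 10 + ["indolent"] * 20
    model = train_logistic(x, y, ridge_penalty=0.0)
    intercept, slope = model.params["coefficients"]
    assert intercept == pytest.approx(np.log(0.5), abs=1e-6)
    assert slope == pytest.approx(np.log(4.0), abs=1e-6)


def test_logistic_constant_feature_gives_prevalence_intercept():
    x = pd.DataFrame({"x": [1.0] * 10})
    y = ["lethal"] * 6 + ["indolent"] * 4
    model = train_logistic(x, y, ridge_penalty=0.0)
    intercept, slope = model.params["coefficients"]
    assert intercept + slope == pytest.approx(np.log(6 / 4), abs=1e-6)


def test_logistic_separation_falls_back_to_ridge():
    x = pd.DataFrame({"x": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]})
    y = ["indolent"] * 3 + ["lethal"] * 3
    model = train_logistic(x, y, ridge_penalty=0.0)
    assert model.params["ridge_fallback"]
    assert np.isfinite(model.params["coefficients"]).all()


def test_encode_clinical_reference_coding(small_cohort):
    cohort, _ = small_cohort
    ids = cohort.phenotype.sample_ids[:10]
    design = encode_clinical(cohort.phenotype, ids,
                             ["age", "gleason_category", "erg_status"])
    assert list(design.columns) == ["age", "gleason_G7", "gleason_G8_10", "erg_rearranged"]
    sub = cohort.phenotype.subset(ids).table
    np.testing.assert_array_equal(
        design["gleason_G7"].to_numpy(), (sub["gleason_category"] == "G7").to_numpy()
    )


# ---------------------------------------------------------------------------
# cross-family properties

def _trained_models(cohort):
    labels = cohort.phenotype.outcomes().to_numpy()
    expr = cohort.expression
    genes = expr.gene_ids[:30]
    sub = expr.subset_genes(genes)
    return sub, labels, [
        train_dlda(sub, labels),
        train_knn(sub, labels, k=5),
        train_ntp(sub, labels),
    ]


def test_scores_invariant_to_nonselected_gene_shift(small_cohort):
    cohort, _ = small_cohort
    sub, labels, models = _trained_models(cohort)
    shifted = cohort.expression.values.copy()
    shifted.loc["G00150"] += 100.0  # not among the selected 30 genes
    shifted_expr = ExpressionMatrix(shifted)
    for model in models:
        np.testing.assert_allclose(
            score(model, cohort.expression), score(model, shifted_expr)
        )


def test_score_permutation_equivariance(small_cohort):
    cohort, _ = small_cohort
    sub, labels, models = _trained_models(cohort)
    perm = np.random.default_rng(0).permutation(sub.sample_ids)
    for model in models:
        s = pd.Series(score(model, sub), index=sub.sample_ids)
        sp = pd.Series(score(model, sub.subset_samples(perm)), index=perm)
        np.testing.assert_allclose(sp.loc[sub.sample_ids], s)


def test_missing_selected_gene_raises(small_cohort):
    cohort, _ = small_cohort
    sub, labels, models = _trained_models(cohort)
    truncated = sub.subset_genes(sub.gene_ids[1:])
    for model in models:
        with pytest.raises(ScoringError):
            score(model, truncated)


def test_training_auc_is_one_on_separable_data():
    train = expr_1d([0, 1, 2, 10, 11, 12])
    labels = ["indolent"] * 3 + ["lethal"] * 3
    model = train_dlda(train, labels)
    assert auc(score(model, train), labels) == 1.0


def test_dlda_rescaling_equivariance(small_cohort):
    """Per-gene affine rescaling of the data, with the model refit, leaves
    DLDA scores unchanged (its per-gene standardization absorbs it)."""
    cohort, _ = small_cohort
    labels = cohort.phenotype.outcomes().to_numpy()
    sub = cohort.expression.subset_genes(cohort.expression.gene_ids[:20])
    rng = np.random.default_rng(4)
    scale = rng.uniform(0.5, 3.0, sub.n_genes)
    shift = rng.normal(0, 5, sub.n_genes)
    rescaled = ExpressionMatrix(sub.values.mul(scale, axis=0).add(shift, axis=0))
    s1 = score(train_dlda(sub, labels), sub)
    s2 = score(train_dlda(rescaled, labels), rescaled)
    np.testing.assert_allclose(s1, s2, rtol=1e-8)


# ---------------------------------------------------------------------------
# plug-in contract and serialization

def test_plugin_contract_runs_through_score():
    from sklearn.svm import SVC

    cohort, _ = generate_cohort(small_config(seed=21))
    labels = cohort.phenotype.outcomes().to_numpy()
    genes = cohort.expression.gene_ids[:20]
    x = cohort.expression.subset_genes(genes).values.to_numpy().T
    clf = SVC(kernel="linear").fit(x, labels == "lethal")
    model = make_plugin_model(
        clf, lambda fitted, feats: fitted.decision_function(feats.to_numpy()), genes
    )
    s = score(model, cohort.expression)
    assert s.shape == (cohort.expression.n_samples,)
    assert auc(s, labels) > 0.9


@pytest.mark.parametrize("family", ["dlda", "knn", "ntp", "logistic"])
def test_serialization_round_trip_preserves_scores(family, small_cohort):
    cohort, _ = small_cohort
    labels = cohort.phenotype.outcomes().to_numpy()
    sub = cohort.expression.subset_genes(cohort.expression.gene_ids[:15])
    if family == "logistic":
        feats = pd.DataFrame(sub.values.to_numpy().T, columns=sub.gene_ids,
                             index=sub.sample_ids)
        model = train_logistic(feats, labels)
        test_input = feats
    else:
        trainer = {"dlda": train_dlda, "ntp": train_ntp}.get(family)
        model = trainer(sub, labels) if trainer else train_knn(sub, labels, k=3)
        test_input = sub
    restored = deserialize_model(serialize_model(model))
    np.testing.assert_allclose(
        score(model, test_input), score(restored, test_input), rtol=1e-12
    )


def test_model_spec_contract():
    with pytest.raises(ValueError):
        ModelSpec("dlda", clinical_fields=("age",))
    with pytest.raises(ValueError):
        ModelSpec("logistic", feature_policy="combined")
    with pytest.raises(ValueError):
        ModelSpec("boosted_trees")
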