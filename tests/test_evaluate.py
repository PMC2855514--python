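import itertools

import numpy as np
import pandas as pd
import pytest

from progsig import (
    ModelSpec,
    SelectionConfig,
    auc,
    generate_cohort,
    make_fold_plans,
    run_cv,
    select_best_model,
    select_features_in_fold,
    split_learning_validation,
    validate_final,
)
from progsig.evaluate import EvaluationReport, UndefinedAUCError

from conftest import permute_outcomes, small_config


# ---------------------------------------------------------------------------
# splitting and fold plans

def test_split_exact_stratification(small_cohort):
    cohort, _ = small_cohort
    learning, validation = split_learning_validation(cohort.phenotype, 0.5, seed=1)
    labels = cohort.phenotype.outcomes()
    for side in (learning, validation):
        counts = labels.loc[side].value_counts()
        assert abs(counts["lethal"] - 35 / 2) <= 0.5
        assert abs(counts["indolent"] - 25 / 2) <= 0.5
    assert set(learning) | set(validation) == set(labels.index)
    assert not set(learning) & set(validation)


def test_split_deterministic_and_study_shape():
    cohort, _ = generate_cohort(small_config(
        n_lethal=165, n_indolent=116, n_genes=5, n_signal_genes=0
    ))
    a = split_learning_validation(cohort.phenotype, 0.5, seed=9)
    b = split_learning_validation(cohort.phenotype, 0.5, seed=9)
    assert a == b
    labels = cohort.phenotype.outcomes()
    counts = labels.loc[a[0]].value_counts()
    assert counts["lethal"] in (82, 83) and counts["indolent"] == 58


def test_split_rejects_emptying_fraction():
    cohort, _ = generate_cohort(small_config(n_lethal=3, n_indolent=3, n_genes=5,
                                             n_signal_genes=0))
    with pytest.raises(ValueError):
        split_learning_validation(cohort.phenotype, 0.01, seed=0)


def test_fold_plans_partition_and_stratification():
    labels = pd.Series(["lethal"] * 23 + ["indolent"] * 17,
                       index=[f"S{i}" for i in range(40)])
    plans = make_fold_plans(labels, k=10, repetitions=3, seed=0)
    assert len(plans) == 30
    for rep in (1, 2, 3):
        rep_plans = [p for p in plans if p.repetition_index == rep]
        test_ids = list(itertools.chain.from_iterable(p.test_ids for p in rep_plans))
        assert sorted(test_ids) == sorted(labels.index)  # disjoint cover
        for p in rep_plans:
            fold_labels = labels.loc[list(p.test_ids)]
            assert 2 <= (fold_labels == "lethal").sum() <= 3
            assert 1 <= (fold_labels == "indolent").sum() <= 2
            assert set(p.train_ids) == set(labels.index) - set(p.test_ids)


def test_fold_plan_count_matches_protocol():
    labels = pd.Series(["lethal"] * 40 + ["indolent"] * 30,
                       index=[f"S{i}" for i in range(70)])
    plans = make_fold_plans(labels, k=10, repetitions=100, seed=1)
    assert len(plans) == 1000
    reps = {p.repetition_index for p in plans}
    assert reps == set(range(1, 101))


# ---------------------------------------------------------------------------
# AUC

def exhaustive_pairwise_auc(scores, labels):
    """Oracle: count concordant pairs plus half ties over all pairs."""
    pos = [s for s, l in zip(scores, labels) if l == "lethal"]
    neg = [s for s, l in zip(scores, labels) if l == "indolent"]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else 0.5 if sp == sn else 0.0
    return total / (len(pos) * len(neg))


@pytest.mark.parametrize("scores,labels,expected", [
    ([10, 9, 2, 1], ["lethal", "lethal", "indolent", "indolent"], 1.0),
    ([1, 1, 1, 1], ["lethal", "lethal", "indolent", "indolent"], 0.5),
    ([0.9, 0.4, 0.8, 0.3], ["lethal", "lethal", "indolent", "indolent"], 0.75),
])
def test_auc_anchors(scores, labels, expected):
    assert auc(scores, labels) == pytest.approx(expected)


def test_auc_matches_pairwise_oracle_on_random_instances():
    rng = np.random.default_rng(11)
    for _ in range(500):
        n = rng.integers(4, 15)
        labels = ["lethal" if v else "indolent" for v in rng.integers(0, 2, n)]
        if "lethal" not in labels or "indolent" not in labels:
            continue
        scores = rng.integers(0, 5, n).astype(float)  # integer scores force ties
        assert auc(scores, labels) == pytest.approx(
            exhaustive_pairwise_auc(scores, labels), abs=1e-14
        )


def test_auc_one_class_undefined():
    with pytest.raises(UndefinedAUCError):
        auc([1, 2], ["lethal", "lethal"])


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(12)
    scores = rng.normal(size=30)
    labels = ["lethal" if v else "indolent" for v in rng.integers(0, 2, 30)]
    base = auc(scores, labels)
    assert auc(np.exp(scores), labels) == pytest.approx(base)
    assert auc(3 * scores - 7, labels) == pytest.approx(base)


# ---------------------------------------------------------------------------
# in-fold feature selection

def test_null_selection_matches_false_positive_rate():
    """On permuted labels the threshold rule keeps ~ m*alpha genes."""
    counts = []
    for seed in range(10):
        cohort, _ = generate_cohort(small_config(
            n_genes=2000, n_signal_genes=0, n_lethal=40, n_indolent=30, seed=seed
        ))
        labels = cohort.phenotype.outcomes()
        genes = select_features_in_fold(
            cohort.expression, labels, labels.index, SelectionConfig(p_threshold=0.01)
        )
        counts.append(len(genes))
    assert np.mean(counts) == pytest.approx(20, abs=8)  # m*alpha = 2000*0.01


def test_planted_signal_enriched_in_selection(small_cohort):
    cohort, truth = small_cohort
    labels = cohort.phenotype.outcomes()
    selected = select_features_in_fold(
        cohort.expression, labels, labels.index, SelectionConfig(p_threshold=0.01)
    )
    planted = set(truth.signal_gene_ids[0])
    hit_rate = len(planted & set(selected)) / len(planted)
    background = (len(selected) - len(planted & set(selected))) / (200 - len(planted))
    assert hit_rate > 0.5
    assert hit_rate > 10 * max(background, 1e-9)


def test_stepwise_prefers_fewest_genes_at_equal_auc():
    """One hugely informative gene plus uninformative ones: stepwise stops
    at the single-gene set."""
    rng = np.random.default_rng(5)
    n = 60
    labels_arr = np.array(["lethal"] * 30 + ["indolent"] * 30)
    strong = np.where(labels_arr == "lethal", 5.0, -5.0) + rng.normal(0, 0.1, n)
    noise = rng.normal(0, 1, (30, n))
    weak = np.where(labels_arr == "lethal", 0.8, -0.8) + rng.normal(0, 1.0, n)
    values = np.vstack([strong, weak, noise])
    import progsig
    expr = progsig.ExpressionMatrix(pd.DataFrame(
        values, index=[f"G{i}" for i in range(32)],
        columns=[f"S{j}" for j in range(n)],
    ))
    labels = pd.Series(labels_arr, index=expr.sample_ids)
    selected = select_features_in_fold(
        expr, labels, expr.sample_ids,
        SelectionConfig(p_threshold=0.01, mode="stepwise", max_genes=10),
    )
    assert selected == ["G0"]


def test_selection_never_reads_test_samples(small_null_cohort):
    """Poisoning the held-out samples with an outcome-revealing constant
    must not change what gets selected from the training slice."""
    cohort, _ = small_null_cohort
    labels = cohort.phenotype.outcomes()
    train_ids = cohort.expression.sample_ids[:40]
    test_ids = cohort.expression.sample_ids[40:]
    poisoned = cohort.expression.values.copy()
    is_lethal = (labels.loc[test_ids] == "lethal").to_numpy()
    poisoned.loc[:, np.array(test_ids)[is_lethal]] += 1000.0
    import progsig
    poisoned_expr = progsig.ExpressionMatrix(poisoned)
    cfg = SelectionConfig(p_threshold=0.05)
    clean = select_features_in_fold(cohort.expression, labels, train_ids, cfg)
    dirty = select_features_in_fold(poisoned_expr, labels, train_ids, cfg)
    assert clean == dirty


# ---------------------------------------------------------------------------
# run_cv and model selection

SPECS = [
    ModelSpec("dlda", name="dlda"),
    ModelSpec("knn", {"k": 5}, name="knn5"),
    ModelSpec("ntp", name="ntp"),
    ModelSpec("logistic", name="lr"),
]


def test_run_cv_strong_signal_auc(small_cohort):
    cohort, _ = small_cohort
    labels = cohort.phenotype.outcomes()
    plans = make_fold_plans(labels, k=5, repetitions=3, seed=2)
    report = run_cv(cohort, [ModelSpec("dlda", name="dlda")], plans,
                    SelectionConfig(p_threshold=0.01))
    assert report.summary.loc[0, "grand_mean_auc"] > 0.9


def test_run_cv_null_honest_vs_leaky(small_null_cohort):
    cohort, _ = small_null_cohort
    cohort = permute_outcomes(cohort, seed=17)
    labels = cohort.phenotype.outcomes()
    plans = make_fold_plans(labels, k=5, repetitions=5, seed=3)
    cfg = SelectionConfig(p_threshold=0.05)
    honest = run_cv(cohort, SPECS, plans, cfg)
    leaky = run_cv(cohort, SPECS, plans, cfg, leaky=True)
    merged = honest.summary.merge(leaky.summary, on="model", suffixes=("_h", "_l"))
    assert (merged["grand_mean_auc_h"] < 0.62).all()
    assert (merged["grand_mean_auc_l"] - merged["grand_mean_auc_h"] > 0.1).all()


def test_cv_auc_monotone_in_effect_size():
    grand = []
    for delta in (0.0, 0.5, 1.0, 2.0):
        cohort, _ = generate_cohort(small_config(effect_size_delta=delta, seed=23))
        labels = cohort.phenotype.outcomes()
        plans = make_fold_plans(labels, k=5, repetitions=2, seed=4)
        report = run_cv(cohort, [ModelSpec("dlda", name="dlda")], plans,
                        SelectionConfig(p_threshold=0.05))
        grand.append(report.summary.loc[0, "grand_mean_auc"])
    assert grand[0] < 0.65
    assert grand[3] > grand[1] and grand[3] > grand[0]
    assert grand[2] >= grand[1] - 0.05  # monotone within Monte-Carlo slack


def _report_from(rows):
    per_rep = pd.DataFrame(rows)
    summary = per_rep.groupby("model", as_index=False)["mean_auc"].agg(
        grand_mean_auc="mean", sd_auc="std")
    summary["mean_n_genes"] = [r["n_genes"] for r in
                               ({row["model"]: row for row in rows}).values()]
    per_fold = pd.DataFrame(columns=["model", "repetition", "fold", "auc", "n_genes"])
    return EvaluationReport(per_fold, per_rep, summary)


def test_select_best_model_argmax_and_ties():
    specs = [ModelSpec("dlda", name="a"), ModelSpec("ntp", name="b")]
    report = _report_from([
        dict(model="a", repetition=1, mean_auc=0.76, n_genes=20),
        dict(model="b", repetition=1, mean_auc=0.71, n_genes=5),
    ])
    assert select_best_model(report, specs).label == "a"
    tie = _report_from([
        dict(model="a", repetition=1, mean_auc=0.75, n_genes=18),
        dict(model="b", repetition=1, mean_auc=0.75, n_genes=12),
    ])
    assert select_best_model(tie, specs).label == "b"  # fewer genes wins
    single = _report_from([dict(model="a", repetition=1, mean_auc=0.6, n_genes=3)])
    assert select_best_model(single, specs[:1]).label == "a"


# ---------------------------------------------------------------------------
# final validation

def test_validate_final_separable_and_deterministic(small_cohort):
    cohort, _ = small_cohort
    learning, validation = split_learning_validation(cohort.phenotype, 0.5, seed=5)
    result = validate_final(
        cohort, learning, validation, ModelSpec("dlda", name="dlda"),
        SelectionConfig(p_threshold=0.01), bootstrap_reps=200, seed=6,
    )
    assert result["auc"] > 0.9
    assert result["bootstrap_ci"][1] <= 1.0
    again = validate_final(
        cohort, learning, validation, ModelSpec("dlda", name="dlda"),
        SelectionConfig(p_threshold=0.01), bootstrap_reps=200, seed=6,
    )
    assert result["bootstrap_ci"] == again["bootstrap_ci"]


def test_validate_final_null_ci_covers_half():
    """At 95% nominal, the bootstrap CI covers 0.5 in >=90% of null
    cohorts (coverage simulation over seeds)."""
    covered = 0
    n_sim = 30
    for seed in range(n_sim):
        cohort, _ = generate_cohort(small_config(
            effect_size_delta=0.0, n_genes=300, seed=100 + seed
        ))
        learning, validation = split_learning_validation(cohort.phenotype, 0.5, seed=seed)
        try:
            result = validate_final(
                cohort, learning, validation, ModelSpec("dlda", name="dlda"),
                SelectionConfig(p_threshold=0.10), bootstrap_reps=200, seed=seed,
            )
        except ValueError:  # empty selection on a null Learning set
            covered += 1  # no model, no claim: count as non-rejection
            continue
        lo, hi = result["bootstrap_ci"]
        covered += lo <= 0.5 <= hi
    assert covered >= 0.9 * n_sim
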