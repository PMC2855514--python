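"""Split-sample evaluation with iterated stratified cross-validation.

The protocol: the cohort is split once into a Learning and a Validation
set (stratified by outcome); within the Learning set, stratified k-fold
cross-validation is repeated R times (default 10 folds x 100 repetitions
= 1000 partitions); in every fold, differentially expressed genes are
selected on the training slice only — the anti-leakage contract — a model
is fitted and the held-out fold scored by AUC; per-repetition means are
aggregated into a grand mean per model; the best model is refit on the
full Learning set and evaluated once on the Validation set with bootstrap
and CV-distribution confidence intervals.

A deliberately leaky mode (feature selection once on the whole Learning
set, test folds included) is provided purely to demonstrate the selection
bias the honest protocol avoids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortDataset, ExpressionMatrix, PhenotypeTable
from .models import (
    ModelSpec,
    TrainedModel,
    encode_clinical,
    score,
    train_dlda,
    train_knn,
    train_logistic,
    train_ntp,
)
from .stats import gene_t_tests_matrix

logger = logging.getLogger(__name__)


class UndefinedAUCError(ValueError):
    """AUC is undefined when one class is absent."""


@dataclass(frozen=True)
class FoldPlan:
    """One train/test partition of one repetition."""

    repetition_index: int  # 1..R
    fold_index: int        # 1..k
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass
class SelectionConfig:
    """In-fold feature-selection settings."""

    p_threshold: float = 0.01
    mode: str = "threshold"  # threshold | stepwise
    stepwise_inner_folds: int = 5
    max_genes: int = 50
    welch: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0,1)")
        if self.mode not in ("threshold", "stepwise"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.max_genes <= 0 or self.stepwise_inner_folds <= 1:
            raise ValueError("caps must be positive (inner folds >= 2)")


@dataclass
class EvaluationReport:
    """Per (model x repetition) mean test AUCs plus aggregates."""

    per_fold: pd.DataFrame        # columns: model, repetition, fold, auc, n_genes
    per_repetition: pd.DataFrame  # columns: model, repetition, mean_auc
    summary: pd.DataFrame         # columns: model, grand_mean_auc, sd_auc, mean_n_genes
    n_failed_folds: int = 0
    chosen_model: str | None = None
    validation: dict = field(default_factory=dict)

    def repetition_aucs(self, model_label: str) -> np.ndarray:
        sel = self.per_repetition["model"] == model_label
        return self.per_repetition.loc[sel, "mean_auc"].to_numpy()


# ---------------------------------------------------------------------------
# partitioning

def split_learning_validation(
    phenotype: PhenotypeTable, learning_fraction: float = 0.5, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified Learning/Validation split; per-class Learning counts are
    round(fraction * class size), so within +-1 of the exact target."""
    if not 0.0 < learning_fraction < 1.0:
        raise ValueError("learning_fraction must be in (0,1)")
    rng = np.random.default_rng(seed)
    df = phenotype.table
    learning: list[str] = []
    validation: list[str] = []
    for outcome in ("lethal", "indolent"):
        ids = df.loc[df["outcome"] == outcome, "sample_id"].to_numpy()
        if len(ids) < 2:
            raise ValueError(f"need >=2 {outcome} samples to split")
        n_learn = int(round(learning_fraction * len(ids)))
        if n_learn == 0 or n_learn == len(ids):
            raise ValueError(
                f"learning_fraction={learning_fraction} empties one side for {outcome}"
            )
        perm = rng.permutation(len(ids))
        learning += list(ids[perm[:n_learn]])
        validation += list(ids[perm[n_learn:]])
    order = {s: i for i, s in enumerate(df["sample_id"])}
    return sorted(learning, key=order.get), sorted(validation, key=order.get)


def make_fold_plans(
    learning_labels: pd.Series, k: int = 10, repetitions: int = 100, seed: int = 0
) -> list[FoldPlan]:
    """R repetitions of a stratified k-fold partition of the Learning set.

    Per repetition the samples of each class are shuffled and dealt to the
    k folds round-robin, so each test fold's class counts are within +-1
    of exact proportionality and the folds partition the Learning set.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = np.asarray(learning_labels.index)
    labels = np.asarray(learning_labels.to_numpy())
    rng = np.random.default_rng(seed)
    plans: list[FoldPlan] = []
    for rep in range(1, repetitions + 1):
        folds: list[list[str]] = [[] for _ in range(k)]
        offset = 0
        for outcome in ("lethal", "indolent"):
            cls = ids[labels == outcome]
            perm = rng.permutation(len(cls))
            for i, idx in enumerate(perm):
                folds[(i + offset) % k].append(cls[idx])
            offset += len(cls)  # stagger so small classes spread over folds
        for f, test in enumerate(folds, start=1):
            if not test:
                raise ValueError(f"fold {f} of repetition {rep} is empty")
            test_set = set(test)
            train = [s for s in ids if s not in test_set]
            train_labels = set(labels[np.isin(ids, train)])
            if train_labels != {"lethal", "indolent"}:
                raise ValueError(f"fold {f} leaves a class absent from training")
            plans.append(FoldPlan(rep, f, tuple(train), tuple(test)))
    return plans


# ---------------------------------------------------------------------------
# AUC

def auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Mann-Whitney AUC: (concordant pairs + half ties) / (n1 * n0),
    probability that a random lethal sample outranks a random indolent
    one."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos, neg = y == "lethal", y == "indolent"
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("AUC needs both classes present")
    ranks = sps.rankdata(s)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# in-fold feature selection

def select_features_in_fold(
    expr: ExpressionMatrix,
    labels: pd.Series,
    train_ids: Sequence[str],
    config: SelectionConfig,
) -> list[str]:
    """Select genes using the training slice only.

    threshold mode: genes with two-sided t-test p below the threshold.
    stepwise mode: genes sorted by p are added one at a time; candidate set
    sizes are scored by inner stratified CV AUC (DLDA) on the training
    slice, and the smallest set attaining the maximal inner AUC wins.
    Returns [] when nothing passes (caller decides the fallback).
    """
    train = expr.subset_samples(train_ids).drop_missing_genes()
    y = labels.loc[list(train_ids)].to_numpy() == "lethal"
    _, p = gene_t_tests_matrix(train.values.to_numpy(), y, welch=config.welch)
    genes = np.asarray(train.gene_ids)
    passing = p < config.p_threshold
    if not passing.any():
        return []
    order = np.argsort(p[passing], kind="stable")
    candidates = list(genes[passing][order])
    if config.mode == "threshold":
        return candidates
    candidates = candidates[: config.max_genes]
    inner_labels = labels.loc[list(train_ids)]
    inner_plans = make_fold_plans(
        inner_labels, k=config.stepwise_inner_folds, repetitions=1,
        seed=len(train_ids),  # deterministic, derived from the slice
    )
    best_auc, best_size = -1.0, 1
    for size in range(1, len(candidates) + 1):
        subset = candidates[:size]
        fold_aucs = []
        for plan in inner_plans:
            sub_train = train.subset_genes(subset).subset_samples(plan.train_ids)
            model = train_dlda(sub_train, inner_labels.loc[list(plan.train_ids)])
            test_expr = train.subset_genes(subset).subset_samples(plan.test_ids)
            try:
                fold_aucs.append(
                    auc(score(model, test_expr), inner_labels.loc[list(plan.test_ids)])
                )
            except UndefinedAUCError:
                continue
        mean_auc = float(np.mean(fold_aucs)) if fold_aucs else 0.0
        if mean_auc > best_auc + 1e-12:  # strictly better: smaller set wins ties
            best_auc, best_size = mean_auc, size
    return candidates[:best_size]


# ---------------------------------------------------------------------------
# model fitting dispatch

def _fit_and_score(
    spec: ModelSpec,
    dataset: CohortDataset,
    genes: list[str],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
) -> np.ndarray:
    labels = dataset.phenotype.outcomes()
    train_labels = labels.loc[list(train_ids)]
    expr = dataset.expression
    if spec.family == "logistic":
        blocks_train, blocks_test = [], []
        if spec.feature_policy != "clinical_only" and genes:
            sub = expr.subset_genes(genes)
            blocks_train.append(pd.DataFrame(
                sub.subset_samples(train_ids).values.to_numpy().T,
                index=list(train_ids), columns=genes,
            ))
            blocks_test.append(pd.DataFrame(
                sub.subset_samples(test_ids).values.to_numpy().T,
                index=list(test_ids), columns=genes,
            ))
        if spec.clinical_fields:
            blocks_train.append(
                encode_clinical(dataset.phenotype, train_ids, spec.clinical_fields)
            )
            blocks_test.append(
                encode_clinical(dataset.phenotype, test_ids, spec.clinical_fields)
            )
        x_train = pd.concat(blocks_train, axis=1)
        x_test = pd.concat(blocks_test, axis=1)
        model = train_logistic(
            x_train, train_labels,
            ridge_penalty=float(spec.hyperparameters.get("ridge_penalty", 1e-4)),
        )
        return score(model, x_test)
    # expression-only families
    sub = expr.subset_genes(genes)
    train_expr = sub.subset_samples(train_ids)
    test_expr = sub.subset_samples(test_ids)
    if spec.family == "dlda":
        model = train_dlda(train_expr, train_labels)
    elif spec.family == "knn":
        model = train_knn(train_expr, train_labels, k=int(spec.hyperparameters.get("k", 3)))
    elif spec.family == "ntp":
        model = train_ntp(train_expr, train_labels)
    elif spec.family == "plugin":
        train_fn: Callable = spec.hyperparameters["train_fn"]  # type: ignore[index]
        model = train_fn(train_expr, train_labels, spec.hyperparameters)
    else:
        raise ValueError(f"unknown family {spec.family!r}")
    return score(model, test_expr)


def fit_spec(
    spec: ModelSpec, dataset: CohortDataset, genes: list[str], train_ids: Sequence[str]
) -> TrainedModel:
    """Fit one spec on a sample set (used for the final Learning-set refit)."""
    labels = dataset.phenotype.outcomes().loc[list(train_ids)]
    if spec.family == "logistic":
        blocks = []
        if spec.feature_policy != "clinical_only" and genes:
            sub = dataset.expression.subset_genes(genes).subset_samples(train_ids)
            blocks.append(pd.DataFrame(
                sub.values.to_numpy().T, index=list(train_ids), columns=genes
            ))
        if spec.clinical_fields:
            blocks.append(encode_clinical(dataset.phenotype, train_ids, spec.clinical_fields))
        return train_logistic(
            pd.concat(blocks, axis=1), labels,
            ridge_penalty=float(spec.hyperparameters.get("ridge_penalty", 1e-4)),
        )
    train_expr = dataset.expression.subset_genes(genes).subset_samples(train_ids)
    if spec.family == "dlda":
        return train_dlda(train_expr, labels)
    if spec.family == "knn":
        return train_knn(train_expr, labels, k=int(spec.hyperparameters.get("k", 3)))
    if spec.family == "ntp":
        return train_ntp(train_expr, labels)
    raise ValueError(f"final refit unsupported for family {spec.family!r}")


# ---------------------------------------------------------------------------
# the cross-validation engine

def run_cv(
    dataset: CohortDataset,
    model_specs: Sequence[ModelSpec],
    fold_plans: Sequence[FoldPlan],
    selection_config: SelectionConfig | None = None,
    leaky: bool = False,
) -> EvaluationReport:
    """Evaluate model specs over the fold plans with in-fold selection.

    ``leaky=True`` selects features ONCE on the union of all samples in
    the plans (training and test folds alike) — the biased shortcut the
    honest protocol exists to avoid; it is here only so the bias can be
    measured.  Single-fold failures are recorded and skipped, not fatal.
    """
    selection_config = selection_config or SelectionConfig()
    dataset.require_aligned()
    labels = dataset.phenotype.outcomes()
    expr = dataset.expression

    leaky_genes: list[str] | None = None
    if leaky:
        all_ids = sorted(
            {s for plan in fold_plans for s in plan.train_ids + plan.test_ids},
            key={s: i for i, s in enumerate(expr.sample_ids)}.get,
        )
        leaky_genes = select_features_in_fold(expr, labels, all_ids, selection_config)

    rows = []
    n_failed = 0
    needs_genes = [s for s in model_specs if s.feature_policy != "clinical_only"]
    for plan in fold_plans:
        genes: list[str] = []
        if needs_genes:
            genes = leaky_genes if leaky else select_features_in_fold(
                expr, labels, plan.train_ids, selection_config
            )
        for spec in model_specs:
            if spec.feature_policy != "clinical_only" and not genes:
                n_failed += 1
                logger.warning(
                    "rep %d fold %d: empty gene selection, skipping %s",
                    plan.repetition_index, plan.fold_index, spec.label,
                )
                continue
            try:
                test_scores = _fit_and_score(
                    spec, dataset, genes, plan.train_ids, plan.test_ids
                )
                fold_auc = auc(test_scores, labels.loc[list(plan.test_ids)])
            except (ValueError, KeyError) as exc:
                n_failed += 1
                logger.warning(
                    "rep %d fold %d failed for %s: %s",
                    plan.repetition_index, plan.fold_index, spec.label, exc,
                )
                continue
            rows.append(dict(
                model=spec.label, repetition=plan.repetition_index,
                fold=plan.fold_index, auc=fold_auc,
                n_genes=len(genes) if spec.feature_policy != "clinical_only" else 0,
            ))
    per_fold = pd.DataFrame(rows, columns=["model", "repetition", "fold", "auc", "n_genes"])
    if per_fold.empty:
        raise ValueError("every fold failed; no results to aggregate")
    per_rep = (
        per_fold.groupby(["model", "repetition"], as_index=False)["auc"]
        .mean().rename(columns={"auc": "mean_auc"})
    )
    summary = (
        per_rep.groupby("model", as_index=False)["mean_auc"]
        .agg(grand_mean_auc="mean", sd_auc="std")
    )
    summary = summary.merge(
        per_fold.groupby("model", as_index=False)["n_genes"].mean()
        .rename(columns={"n_genes": "mean_n_genes"}),
        on="model",
    )
    return EvaluationReport(per_fold, per_rep, summary, n_failed_folds=n_failed)


_FAMILY_ORDER = {f: i for i, f in enumerate(("dlda", "logistic", "ntp", "knn", "plugin"))}


def select_best_model(report: EvaluationReport, specs: Sequence[ModelSpec]) -> ModelSpec:
    """Maximal grand-mean AUC; ties break toward fewer mean selected genes,
    then the documented family order."""
    if report.summary.empty:
        raise ValueError("empty evaluation report")
    by_label = {s.label: s for s in specs}

    def sort_key(row) -> tuple:
        spec = by_label[row["model"]]
        return (-row["grand_mean_auc"], row["mean_n_genes"], _FAMILY_ORDER[spec.family])

    best_row = min(report.summary.to_dict("records"), key=sort_key)
    return by_label[best_row["model"]]


def validate_final(
    dataset: CohortDataset,
    learning_ids: Sequence[str],
    validation_ids: Sequence[str],
    spec: ModelSpec,
    selection_config: SelectionConfig | None = None,
    bootstrap_reps: int = 2000,
    seed: int = 0,
    cv_report: EvaluationReport | None = None,
    confidence: float = 0.95,
) -> dict:
    """Refit the chosen spec on the full Learning set and evaluate it once
    on the Validation set.

    Two confidence intervals are reported, labeled: a stratified bootstrap
    percentile interval over resampled validation samples, and (when a CV
    report is supplied) the percentile interval of the repetition-level CV
    AUC distribution from the Learning set.
    """
    selection_config = selection_config or SelectionConfig()
    labels = dataset.phenotype.outcomes()
    val_labels = labels.loc[list(validation_ids)]
    if set(val_labels) != {"lethal", "indolent"}:
        raise UndefinedAUCError("validation set must contain both classes")
    genes: list[str] = []
    if spec.feature_policy != "clinical_only":
        genes = select_features_in_fold(
            dataset.expression, labels, learning_ids, selection_config
        )
        if not genes:
            raise ValueError("empty feature selection on the Learning set")
    scores = _fit_and_score(spec, dataset, genes, learning_ids, validation_ids)
    point = auc(scores, val_labels)

    rng = np.random.default_rng(seed)
    val_ids = np.asarray(validation_ids)
    pos_idx = np.flatnonzero(val_labels.to_numpy() == "lethal")
    neg_idx = np.flatnonzero(val_labels.to_numpy() == "indolent")
    boot = np.empty(bootstrap_reps)
    scores = np.asarray(scores)
    lab_arr = val_labels.to_numpy()
    for b in range(bootstrap_reps):
        take = np.concatenate([
            rng.choice(pos_idx, len(pos_idx), replace=True),
            rng.choice(neg_idx, len(neg_idx), replace=True),
        ])
        boot[b] = auc(scores[take], lab_arr[take])
    alpha = (1.0 - confidence) / 2.0
    result = dict(
        auc=point,
        n_genes=len(genes),
        selected_genes=genes,
        bootstrap_ci=(
            float(np.quantile(boot, alpha)), float(np.quantile(boot, 1 - alpha))
        ),
        bootstrap_reps=bootstrap_reps,
        seed=seed,
    )
    if cv_report is not None and spec.label in set(cv_report.per_repetition["model"]):
        rep_aucs = cv_report.repetition_aucs(spec.label)
        result["cv_distribution_ci"] = (
            float(np.quantile(rep_aucs, alpha)), float(np.quantile(rep_aucs, 1 - alpha))
        )
    return result
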