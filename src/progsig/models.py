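"""Classifier families producing a continuous lethality score.

Native families: diagonal linear discriminant analysis (DLDA), k-nearest
neighbor, nearest-template prediction (NTP), and ridge-penalized logistic
regression; external learners (SVM, neural networks, ...) attach through a
train/score plug-in contract.  Scoring orientation is fixed throughout:
larger score means more lethal.

All standardization statistics are computed on training data only and
frozen into the trained model — the module-level leakage contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ExpressionMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

FAMILIES = ("dlda", "knn", "ntp", "logistic", "plugin")
CLINICAL_FIELDS = ("age", "gleason_category", "erg_status")

SERIAL_FORMAT_VERSION = 1


class TrainingError(ValueError):
    """Training inputs violate a family's contract."""


class ScoringError(KeyError):
    """A selected feature is missing at scoring time."""


@dataclass(frozen=True)
class ModelSpec:
    """Classifier family + hyperparameters + feature policy."""

    family: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    feature_policy: str = "genes_only"  # genes_only | clinical_only | combined
    clinical_fields: tuple[str, ...] = ()
    name: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.feature_policy not in ("genes_only", "clinical_only", "combined"):
            raise ValueError(f"unknown feature_policy {self.feature_policy!r}")
        if self.feature_policy == "genes_only" and self.clinical_fields:
            raise ValueError("genes_only models cannot carry clinical fields")
        if self.feature_policy != "genes_only" and not self.clinical_fields:
            raise ValueError(f"{self.feature_policy} requires clinical_fields")
        bad = set(self.clinical_fields) - set(CLINICAL_FIELDS)
        if bad:
            raise ValueError(f"unknown clinical fields {sorted(bad)}")

    @property
    def label(self) -> str:
        return self.name or f"{self.family}:{self.feature_policy}"


@dataclass
class TrainedModel:
    """A fitted classifier: spec, selected genes, frozen parameters, and a
    family-specific parameter block."""

    spec: ModelSpec
    selected_gene_ids: list[str]
    params: dict

    def uses_genes(self) -> bool:
        return self.spec.feature_policy != "clinical_only"


def _labels_to_binary(labels: Sequence[str]) -> np.ndarray:
    arr = np.asarray(labels)
    bad = set(arr) - {"lethal", "indolent"}
    if bad:
        raise TrainingError(f"labels must be lethal/indolent, got {sorted(bad)}")
    y = arr == "lethal"
    if y.all() or not y.any():
        raise TrainingError("both outcome classes must be present for training")
    return y


def _gene_matrix(expr: ExpressionMatrix, gene_ids: Sequence[str]) -> np.ndarray:
    missing = [g for g in gene_ids if g not in expr.values.index]
    if missing:
        raise ScoringError(f"missing selected gene(s): {missing[:5]}")
    return expr.values.loc[list(gene_ids)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# clinical design encoding (reference levels G4_6 and negative)

def encode_clinical(
    phenotype: PhenotypeTable, sample_ids: Sequence[str], fields: Sequence[str]
) -> pd.DataFrame:
    """Encode clinical fields into a numeric design block: age linear,
    Gleason and ERG as reference-coded indicators (references G4_6 and
    negative; unknown levels coded at the reference)."""
    sub = phenotype.subset(sample_ids).table
    cols: dict[str, np.ndarray] = {}
    for f in fields:
        if f == "age":
            cols["age"] = sub["age_at_diagnosis"].to_numpy(dtype=float)
        elif f == "gleason_category":
            g = sub["gleason_category"]
            cols["gleason_G7"] = (g == "G7").to_numpy(dtype=float)
            cols["gleason_G8_10"] = (g == "G8_10").to_numpy(dtype=float)
        elif f == "erg_status":
            cols["erg_rearranged"] = (sub["erg_status"] == "rearranged").to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown clinical field {f!r}")
    return pd.DataFrame(cols, index=list(sample_ids))


# ---------------------------------------------------------------------------
# DLDA

def train_dlda(expr: ExpressionMatrix, labels: Sequence[str]) -> TrainedModel:
    """Diagonal LDA: per-class per-gene means with a pooled per-gene
    variance; score(x) = sum_g [(x_g - mu_ind)^2 - (x_g - mu_leth)^2] / s_g^2.
    """
    y = _labels_to_binary(labels)
    if y.sum() < 2 or (~y).sum() < 2:
        raise TrainingError("DLDA needs >=2 samples per class")
    x = expr.values.to_numpy(dtype=float)
    n1, n0 = int(y.sum()), int((~y).sum())
    mu1 = x[:, y].mean(axis=1)
    mu0 = x[:, ~y].mean(axis=1)
    v1 = x[:, y].var(axis=1, ddof=1)
    v0 = x[:, ~y].var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    keep = pooled > 0
    if not keep.all():
        logger.warning("DLDA dropping %d zero-variance gene(s)", int((~keep).sum()))
    if not keep.any():
        raise TrainingError("all genes have zero pooled variance")
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return TrainedModel(
        spec=ModelSpec("dlda"),
        selected_gene_ids=genes,
        params=dict(mu_lethal=mu1[keep], mu_indolent=mu0[keep], pooled_var=pooled[keep]),
    )


def _score_dlda(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    p = model.params
    d_ind = (x - p["mu_indolent"][:, None]) ** 2
    d_let = (x - p["mu_lethal"][:, None]) ** 2
    return ((d_ind - d_let) / p["pooled_var"][:, None]).sum(axis=0)


# ---------------------------------------------------------------------------
# kNN

def train_knn(expr: ExpressionMatrix, labels: Sequence[str], k: int = 3) -> TrainedModel:
    """k-nearest-neighbor on Euclidean distance; score = lethal fraction
    among the k nearest exemplars.  Distance ties break toward the smaller
    training-sample index (stable sort)."""
    if k % 2 == 0:
        raise ValueError("k must be odd")
    y = _labels_to_binary(labels)
    if k > len(y):
        raise ValueError(f"k={k} exceeds n_train={len(y)}")
    return TrainedModel(
        spec=ModelSpec("knn", {"k": k}),
        selected_gene_ids=list(expr.gene_ids),
        params=dict(exemplars=expr.values.to_numpy(dtype=float), y=y, k=k),
    )


def _score_knn(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    p = model.params
    ex, y, k = p["exemplars"], p["y"], p["k"]
    # distances: train x test
    d = np.sqrt(((ex[:, :, None] - x[:, None, :]) ** 2).sum(axis=0))
    out = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        nearest = np.argsort(d[:, j], kind="stable")[:k]
        out[j] = y[nearest].mean()
    return out


# ---------------------------------------------------------------------------
# NTP

def train_ntp(expr: ExpressionMatrix, labels: Sequence[str]) -> TrainedModel:
    """Nearest-template prediction: signed +/-1 templates over the marker
    genes (sign of the training lethal-minus-indolent mean difference),
    samples standardized per gene with training statistics, classified by
    cosine distance; score = d_indolent - d_lethal."""
    if expr.n_genes < 2:
        raise TrainingError("NTP needs >=2 marker genes")
    y = _labels_to_binary(labels)
    x = expr.values.to_numpy(dtype=float)
    diff = x[:, y].mean(axis=1) - x[:, ~y].mean(axis=1)
    if (diff == 0).all():
        raise TrainingError("degenerate templates: all markers have zero mean difference")
    template = np.sign(diff)
    template[template == 0] = 1.0  # zero-difference markers default lethal-up
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    return TrainedModel(
        spec=ModelSpec("ntp"),
        selected_gene_ids=list(expr.gene_ids),
        params=dict(template=template, mean=mean, sd=sd),
    )


def _cosine_distance(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u, axis=0)
    nv = np.linalg.norm(v)
    nu[nu == 0] = 1.0
    return 1.0 - (u * v[:, None]).sum(axis=0) / (nu * (nv if nv else 1.0))


def _score_ntp(model: TrainedModel, x: np.ndarray) -> np.ndarray:
    p = model.params
    z = (x - p["mean"][:, None]) / p["sd"][:, None]
    d_lethal = _cosine_distance(z, p["template"])
    d_indolent = _cosine_distance(z, -p["template"])
    return d_indolent - d_lethal


# ---------------------------------------------------------------------------
# logistic regression (ridge-penalized IRLS)

DEFAULT_RIDGE = 1e-4


def _irls(
    design: np.ndarray, y: np.ndarray, penalty: float, tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, bool]:
    """Penalized maximum likelihood by iteratively reweighted least squares;
    the intercept is never penalized.  Returns (coefficients, converged)."""
    n, p = design.shape
    beta = np.zeros(p)
    pen = np.full(p, penalty)
    pen[0] = 0.0  # column 0 is the intercept
    converged = False
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = design.T @ (y - mu) - pen * beta
        hess = (design.T * w) @ design + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if not np.isfinite(beta).all():
            return beta, False
        if np.abs(step).max() < tol:
            converged = True
            break
    return beta, converged


def train_logistic(
    features: pd.DataFrame, labels: Sequence[str], ridge_penalty: float = DEFAULT_RIDGE
) -> TrainedModel:
    """Logistic regression on a design table mixing selected genes and
    encoded clinical fields.  Non-convergence at penalty 0 (typically
    separation) is reported and the model refit with the default ridge
    penalty; the fallback is flagged in the parameter block."""
    y = _labels_to_binary(labels).astype(float)
    cols = list(features.columns)
    design = np.column_stack([np.ones(len(features)), features.to_numpy(dtype=float)])
    beta, converged = _irls(design, y, ridge_penalty)
    fallback = False
    if not converged:
        if ridge_penalty == 0.0:
            logger.warning(
                "logistic fit did not converge at penalty 0 (separation?); "
                "refitting with ridge=%.1e", DEFAULT_RIDGE,
            )
            beta, converged = _irls(design, y, DEFAULT_RIDGE)
            fallback = True
        if not converged:
            logger.warning("logistic fit did not converge; using last iterate")
    gene_cols = [c for c in cols if not c.startswith(("age", "gleason_", "erg_"))]
    return TrainedModel(
        spec=ModelSpec(
            "logistic", {"ridge_penalty": ridge_penalty},
            feature_policy="genes_only" if len(gene_cols) == len(cols) else "combined"
            if gene_cols else "clinical_only",
            clinical_fields=() if len(gene_cols) == len(cols) else tuple(
                sorted({"age" if c == "age" else
                        "gleason_category" if c.startswith("gleason_") else
                        "erg_status" for c in cols if c not in gene_cols})
            ),
        ),
        selected_gene_ids=gene_cols,
        params=dict(
            coefficients=beta, columns=cols, converged=converged,
            ridge_fallback=fallback,
        ),
    )


def _score_logistic(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    cols = model.params["columns"]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ScoringError(f"missing design column(s): {missing[:5]}")
    design = np.column_stack([np.ones(len(features)), features[cols].to_numpy(dtype=float)])
    return design @ model.params["coefficients"]


# ---------------------------------------------------------------------------
# unified scoring + plug-in contract

PluginTrain = Callable[[pd.DataFrame, Sequence[str], Mapping], object]
PluginScore = Callable[[object, pd.DataFrame], np.ndarray]


def make_plugin_model(
    fitted: object, score_fn: PluginScore, feature_ids: Sequence[str],
    hyperparameters: Mapping | None = None,
) -> TrainedModel:
    """Wrap an externally trained learner (SVM, NN, ...) in the scoring
    contract; ``score_fn(fitted, features)`` must return one score per row,
    larger meaning more lethal."""
    return TrainedModel(
        spec=ModelSpec("plugin", dict(hyperparameters or {})),
        selected_gene_ids=list(feature_ids),
        params=dict(fitted=fitted, score_fn=score_fn),
    )


def score(model: TrainedModel, expr_or_features) -> np.ndarray:
    """Score samples with a trained model; one finite score per sample,
    larger meaning more lethal."""
    family = model.spec.family
    if family == "logistic":
        return _score_logistic(model, expr_or_features)
    if family == "plugin":
        feats = expr_or_features
        if isinstance(feats, ExpressionMatrix):
            feats = pd.DataFrame(
                _gene_matrix(feats, model.selected_gene_ids).T,
                columns=model.selected_gene_ids,
            )
        missing = [c for c in model.selected_gene_ids if c not in feats.columns]
        if missing:
            raise ScoringError(f"missing feature(s): {missing[:5]}")
        return np.asarray(model.params["score_fn"](model.params["fitted"], feats), dtype=float)
    if not isinstance(expr_or_features, ExpressionMatrix):
        raise TypeError(f"{family} models score ExpressionMatrix inputs")
    x = _gene_matrix(expr_or_features, model.selected_gene_ids)
    if family == "dlda":
        out = _score_dlda(model, x)
    elif family == "knn":
        out = _score_knn(model, x)
    elif family == "ntp":
        out = _score_ntp(model, x)
    else:
        raise ValueError(f"unknown family {family!r}")
    if not np.isfinite(out).all():
        raise ScoringError("non-finite score produced")
    return out


# ---------------------------------------------------------------------------
# plain-text serialization

def serialize_model(model: TrainedModel) -> str:
    """Versioned plain-text dump of a trained model (not for plugins)."""
    if model.spec.family == "plugin":
        raise ValueError("plugin models are not text-serializable")
    lines = [
        f"format_version\t{SERIAL_FORMAT_VERSION}",
        f"family\t{model.spec.family}",
        "hyperparameters\t" + ";".join(
            f"{k}={v}" for k, v in sorted(model.spec.hyperparameters.items())
        ),
        "features\t" + ",".join(model.selected_gene_ids),
    ]
    for key, val in sorted(model.params.items()):
        arr = np.asarray(val)
        if arr.dtype.kind in "fiub" and arr.ndim <= 2:
            flat = ",".join(repr(float(v)) for v in arr.ravel())
            lines.append(f"param\t{key}\t{'x'.join(map(str, arr.shape))}\t{flat}")
        elif isinstance(val, (list, tuple)) and all(isinstance(c, str) for c in val):
            lines.append(f"param_str\t{key}\t\t{','.join(val)}")
        elif isinstance(val, (bool, int, float, str)):
            lines.append(f"scalar\t{key}\t{type(val).__name__}\t{val}")
    return "\n".join(lines) + "\n"


def deserialize_model(text: str) -> TrainedModel:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    fields = dict(ln.split("\t", 1) for ln in lines if ln.split("\t")[0]
                  in ("format_version", "family", "hyperparameters", "features"))
    if int(fields["format_version"]) != SERIAL_FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    family = fields["family"]
    hp: dict[str, object] = {}
    if fields.get("hyperparameters"):
        for item in fields["hyperparameters"].split(";"):
            if not item:
                continue
            k, v = item.split("=", 1)
            try:
                hp[k] = int(v)
            except ValueError:
                try:
                    hp[k] = float(v)
                except ValueError:
                    hp[k] = v
    features = fields["features"].split(",") if fields["features"] else []
    params: dict[str, object] = {}
    for ln in lines:
        parts = ln.split("\t")
        if parts[0] == "param":
            _, key, shape, flat = parts
            arr = np.array([float(x) for x in flat.split(",")]) if flat else np.array([])
            if shape and shape != "":
                arr = arr.reshape([int(s) for s in shape.split("x")])
            params[key] = arr
        elif parts[0] == "param_str":
            params[parts[1]] = parts[3].split(",") if parts[3] else []
        elif parts[0] == "scalar":
            _, key, typ, raw = parts
            params[key] = {"bool": lambda s: s == "True", "int": int,
                           "float": float, "str": str}[typ](raw)
    if family == "knn":
        params["y"] = np.asarray(params["y"], dtype=bool)
        params["k"] = int(hp.get("k", 3))
    if family == "logistic":
        params["columns"] = params.get("columns", features)
    model = TrainedModel(spec=ModelSpec(family, hp), selected_gene_ids=features,
                         params=params)
    return model
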