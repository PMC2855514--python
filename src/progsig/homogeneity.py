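"""Silhouette-width homogeneity analysis of outcome classes.

The homogeneity score of a sample is its silhouette width: with a(i) the
mean distance to samples of its own group (self excluded) and b(i) the
mean distance to the other group, s(i) = (b(i) - a(i)) / max(a(i), b(i)).
Group averages grade how "structured" a class is; classes whose members
intermingle with the other class average near (or below) zero.  The
module also provides the deliberately overfit signature selection used to
pick the best class descriptors on a full cohort, and the stroma-cluster
flagging used to screen contaminated bulk samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist, squareform

from .cohort import CohortDataset, ExpressionMatrix
from .stats import compute_q_values, gene_t_tests_matrix

logger = logging.getLogger(__name__)

STRUCTURE_BANDS = (
    (0.70, "strong"),      # > 0.70
    (0.50, "reasonable"),  # (0.50, 0.70]
    (0.25, "weak"),        # (0.25, 0.50]
)


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, finite

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.isfinite(v).all():
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal not zero")
        self.values = v


@dataclass
class SilhouetteResult:
    scores: pd.Series        # per-sample s(i), index = sample ids
    groups: pd.Series        # per-sample group label, same index
    group_averages: dict[str, float]
    overall_average: float


def pairwise_distances(
    expr: ExpressionMatrix,
    gene_subset: Sequence[str] | None = None,
    metric: str = "one_minus_pearson",
) -> DistanceMatrix:
    """Sample-by-sample distances over a gene subset.

    ``one_minus_pearson`` is 1 minus the Pearson correlation of sample
    profiles across the subset; ``euclidean`` is the ordinary distance.
    Genes with missing values are dropped (logged) first.
    """
    sub = expr if gene_subset is None else expr.subset_genes(gene_subset)
    sub = sub.drop_missing_genes()
    x = sub.values.to_numpy(dtype=float).T  # samples x genes
    if metric == "euclidean":
        d = squareform(pdist(x, metric="euclidean"))
    elif metric == "one_minus_pearson":
        if x.shape[1] < 2:
            raise ValueError("correlation metric needs >=2 genes")
        sd = x.std(axis=1)
        if (sd == 0).any():
            bad = sub.sample_ids[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(f"zero-variance sample under correlation metric: {bad!r}")
        d = 1.0 - np.corrcoef(x)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2.0  # symmetrize fp noise
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(sub.sample_ids, d)


def silhouette_widths(dist: DistanceMatrix, groups: Sequence[str]) -> SilhouetteResult:
    """Per-sample homogeneity scores for a two-level grouping.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)), with a(i) the self-excluded
    mean within-group distance; samples in singleton groups score 0 by
    convention.
    """
    g = pd.Series(list(groups), index=dist.sample_ids)
    levels = sorted(set(g))
    if len(levels) < 2:
        raise ValueError("silhouette needs >=2 groups represented")
    d = dist.values
    n = len(g)
    scores = np.zeros(n)
    masks = {lv: (g == lv).to_numpy() for lv in levels}
    for i in range(n):
        own = masks[g.iloc[i]].copy()
        own[i] = False
        if not own.any():  # singleton group
            scores[i] = 0.0
            continue
        a = d[i, own].mean()
        b = min(d[i, masks[lv]].mean() for lv in levels if lv != g.iloc[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    s = pd.Series(scores, index=dist.sample_ids, name="homogeneity_score")
    group_avgs = {lv: float(s[masks[lv]].mean()) for lv in levels}
    return SilhouetteResult(s, g, group_avgs, float(s.mean()))


def group_homogeneity(result: SilhouetteResult) -> tuple[dict[str, float], float]:
    """Per-group average homogeneity scores and the overall average."""
    return dict(result.group_averages), result.overall_average


def structure_category(avg_score: float) -> str:
    """Band an average homogeneity score: >0.70 strong, (0.50,0.70]
    reasonable, (0.25,0.50] weak, <=0.25 none."""
    if not -1.0 <= avg_score <= 1.0:
        raise ValueError(f"average score {avg_score} outside [-1,1]")
    for lo, name in STRUCTURE_BANDS:
        if avg_score > lo + 1e-12:
            return name
    return "none"


def overfit_signature(
    dataset: CohortDataset, q_threshold: float = 0.05, method: str = "storey"
) -> list[str]:
    """Deliberately overfit class descriptors: per-gene t-tests on ALL
    samples of both outcome classes, FDR-corrected; genes with q below the
    threshold, sorted by p.  Useful as the best molecular description of
    the two groups — never as an unbiased classifier input."""
    labels = dataset.phenotype.outcomes()
    keep = labels.isin(["lethal", "indolent"])
    ids = list(labels.index[keep])
    expr = dataset.expression.subset_samples(ids).drop_missing_genes()
    y = labels.loc[ids].to_numpy() == "lethal"
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    _, p = gene_t_tests_matrix(expr.values.to_numpy(), y)
    q = compute_q_values(p, method=method)
    genes = np.asarray(expr.gene_ids)
    hit = q < q_threshold
    order = np.argsort(p[hit], kind="stable")
    return list(genes[hit][order])


def silhouette_plot_data(result: SilhouetteResult) -> pd.DataFrame:
    """Ordered bar records (group, sample, score): descending score within
    each group, ties broken by sample id."""
    df = pd.DataFrame({
        "group": result.groups.to_numpy(),
        "sample": result.scores.index,
        "score": result.scores.to_numpy(),
    })
    df = df.sort_values(
        ["group", "score", "sample"], ascending=[True, False, True], kind="stable"
    )
    return df.reset_index(drop=True)


def plot_silhouette(result: SilhouetteResult, path) -> None:
    """Thin optional rendering of the silhouette plot to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = silhouette_plot_data(result)
    fig, ax = plt.subplots(figsize=(6, max(2, 0.12 * len(data))))
    colors = {g: c for g, c in zip(sorted(set(data["group"])),
                                   plt.rcParams["axes.prop_cycle"].by_key()["color"])}
    ax.barh(range(len(data)), data["score"],
            color=[colors[g] for g in data["group"]])
    ax.set_xlabel("homogeneity score")
    ax.set_yticks([])
    for g, avg in result.group_averages.items():
        ax.axvline(avg, color=colors[g], linestyle="--", linewidth=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class StromaReport:
    flags: pd.Series           # per-sample bool, index = sample ids
    n_flagged: int
    flagged_ids: list[str]
    separation: float          # mean silhouette of the 2-cut clustering
    weak_separation: bool
    n_signature_genes_used: int


def flag_stroma_samples(
    dataset: CohortDataset,
    stroma_gene_ids: Sequence[str],
    metric: str = "one_minus_pearson",
    weak_threshold: float = 0.25,
) -> StromaReport:
    """Flag samples clustering as stroma-like under a stroma signature.

    Average-linkage hierarchical clustering on the signature-gene distance
    matrix, cut into 2 clusters; the cluster with the higher mean
    signature-gene expression is flagged.  The report carries the mean
    silhouette of the 2-cut: below ``weak_threshold`` the separation is
    marked weak and the flags should not be trusted.
    """
    present = [g for g in stroma_gene_ids if g in dataset.expression.values.index]
    if len(present) < 5:
        raise ValueError(
            f"only {len(present)} stroma signature gene(s) present; need >=5"
        )
    if len(present) < len(stroma_gene_ids):
        logger.warning(
            "%d of %d stroma genes absent from the matrix",
            len(stroma_gene_ids) - len(present), len(stroma_gene_ids),
        )
    dist = pairwise_distances(dataset.expression, present, metric=metric)
    linkage = average(squareform(dist.values, checks=False))
    clusters = fcluster(linkage, t=2, criterion="maxclust")
    sub = dataset.expression.subset_genes(present)
    mean_expr = sub.values.to_numpy().mean(axis=0)
    mean_by_cluster = {c: mean_expr[clusters == c].mean() for c in np.unique(clusters)}
    stroma_cluster = max(mean_by_cluster, key=mean_by_cluster.get)
    flags = pd.Series(clusters == stroma_cluster, index=dist.sample_ids, name="stroma")
    if len(np.unique(clusters)) < 2:
        separation = 0.0
    else:
        sil = silhouette_widths(dist, [str(c) for c in clusters])
        separation = sil.overall_average
    return StromaReport(
        flags=flags,
        n_flagged=int(flags.sum()),
        flagged_ids=list(flags.index[flags]),
        separation=float(separation),
        weak_separation=bool(separation < weak_threshold),
        n_signature_genes_used=len(present),
    )
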