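"""Categorical association statistics and univariate gene tests.

Two-sample t-tests (pooled by default, Welch by flag), Storey/BH q-values,
Cramer's V, Fisher's exact test (exact for 2x2, seeded Monte-Carlo with
fixed margins for larger tables), and the odds ratio with a Woolf
(log-scale) confidence interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import UnivariateSpline
from scipy.special import gammaln

logger = logging.getLogger(__name__)


class DegenerateVarianceError(ValueError):
    """Both groups have zero variance but different means."""


class UndefinedOddsRatioError(ValueError):
    """A zero margin makes the odds ratio undefined."""


@dataclass
class ContingencyTable:
    """Labeled r x c table of non-negative integer counts."""

    counts: pd.DataFrame  # index = row labels, columns = col labels

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table needs >=2 rows and >=2 columns")
        if (arr < 0).any():
            raise ValueError("contingency counts must be non-negative")
        if arr.sum() < 1:
            raise ValueError("contingency table grand total must be >=1")

    @classmethod
    def from_arrays(cls, counts, row_labels=None, col_labels=None) -> "ContingencyTable":
        arr = np.asarray(counts)
        return cls(pd.DataFrame(
            arr,
            index=row_labels or [f"r{i}" for i in range(arr.shape[0])],
            columns=col_labels or [f"c{j}" for j in range(arr.shape[1])],
        ))

    @classmethod
    def crosstab(cls, rows: Sequence, cols: Sequence) -> "ContingencyTable":
        return cls(pd.crosstab(pd.Series(rows), pd.Series(cols)))

    def array(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# t-tests

def gene_t_test(
    values_a: Sequence[float], values_b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled variance by default.

    t is antisymmetric in group order, p symmetric.  If both variances are
    zero: equal means give (0, 1) with a warning, unequal means are a
    degenerate-variance error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 non-missing values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            logger.warning("both groups constant and equal; returning t=0, p=1")
            return 0.0, 1.0
        raise DegenerateVarianceError("zero variance in both groups with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def gene_t_tests_matrix(
    values: np.ndarray, is_group_a: np.ndarray, welch: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row (per-gene) two-sample t-test.

    ``values`` is genes x samples with no missing entries; rows where the
    test is undefined (zero pooled variance) get t=0, p=1.
    """
    is_a = np.asarray(is_group_a, dtype=bool)
    xa, xb = values[:, is_a], values[:, ~is_a]
    na, nb = xa.shape[1], xb.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs >=2 samples")
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    if welch:
        se2 = va / na + vb / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se2 = sp2 * (1.0 / na + 1.0 / nb)
        df = np.full(values.shape[0], na + nb - 2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
    bad = ~np.isfinite(t)
    t[bad] = 0.0
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p[bad] = 1.0
    return t, p


# ---------------------------------------------------------------------------
# q-values

def _storey_pi0(p: np.ndarray) -> float:
    """Storey's null-proportion estimate: pi0(lambda) on a grid, smoothed by
    a cubic spline and read off at the largest lambda."""
    m = len(p)
    lam = np.arange(0.05, 0.95, 0.05)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if m < 2 * len(lam):  # tiny families: spline unstable, fall back
        return 1.0
    spline = UnivariateSpline(lam, pi0_lam, k=3)
    pi0 = float(spline(lam[-1]))
    return min(max(pi0, 1.0 / m), 1.0)


def compute_q_values(p_values: Sequence[float], method: str = "storey") -> np.ndarray:
    """FDR q-values for a complete family of p-values.

    ``bh`` is the Benjamini-Hochberg step-up; ``storey`` scales it by the
    estimated null proportion pi0 (so bh equals storey with pi0 pinned at
    1).  Families smaller than 100 tests always use pi0 = 1: the pi0
    estimate is too noisy to help there.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    m = len(p)
    if method == "bh" or (method == "storey" and m < 100):
        pi0 = 1.0
    elif method == "storey":
        pi0 = _storey_pi0(p)
    else:
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# categorical association

def cramers_v(table: ContingencyTable) -> float:
    """Cramer's V from the Pearson chi-square without continuity
    correction; zero-margin rows/columns are dropped with a warning."""
    df = table.counts
    row_ok = df.sum(axis=1) > 0
    col_ok = df.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        logger.warning(
            "dropping %d zero rows and %d zero columns before Cramer's V",
            int((~row_ok).sum()), int((~col_ok).sum()),
        )
        df = df.loc[row_ok, col_ok]
    arr = df.to_numpy(dtype=float)
    n = arr.sum()
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n
    chi2 = ((arr - expected) ** 2 / expected).sum()
    k = min(arr.shape) - 1
    if k == 0:
        return 0.0
    return float(np.sqrt(chi2 / (n * k)))


def fisher_exact(
    table: ContingencyTable, mc_reps: int = 10000, seed: int = 0
) -> tuple[float, float | None]:
    """Fisher's exact test p-value.

    2x2 tables: exact two-sided p as the total hypergeometric probability
    of tables no more likely than the observed one.  r x c tables: seeded
    Monte-Carlo over random tables with the observed margins; returns the
    p-value and its standard error (None for the exact case).
    """
    arr = table.array().astype(int)
    if arr.shape == (2, 2):
        return _fisher_2x2(arr), None
    if mc_reps < 1000:
        raise ValueError("mc_reps must be >= 1000 for r x c tables")
    return _fisher_mc(arr, mc_reps, seed)


def _fisher_2x2(arr: np.ndarray) -> float:
    a = arr[0, 0]
    r1, r2 = arr[0].sum(), arr[1].sum()
    c1 = arr[:, 0].sum()
    n = arr.sum()
    rv = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    # two-sided: tables with probability <= observed's (within fp slack)
    p = probs[probs <= p_obs * (1 + 1e-9)].sum()
    return float(min(p, 1.0))


def _log_table_prob(arr: np.ndarray, lgam_margins: float, lgam_n: float) -> float:
    return lgam_margins - lgam_n - gammaln(arr + 1).sum()


def _fisher_mc(arr: np.ndarray, mc_reps: int, seed: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    rows, cols = arr.sum(axis=1), arr.sum(axis=0)
    lgam_margins = gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
    lgam_n = gammaln(arr.sum() + 1)
    logp_obs = _log_table_prob(arr, lgam_margins, lgam_n)
    hits = 0
    for _ in range(mc_reps):
        sim = sps.random_table(rows, cols).rvs(random_state=rng)
        if _log_table_prob(sim, lgam_margins, lgam_n) <= logp_obs + 1e-9:
            hits += 1
    p = (hits + 1) / (mc_reps + 1)  # add-one to avoid p=0
    se = math.sqrt(p * (1 - p) / mc_reps)
    return float(p), float(se)


def odds_ratio_ci(
    table: ContingencyTable, confidence: float = 0.95
) -> tuple[float, float, float]:
    """Odds ratio of a 2x2 table with a Woolf (log) interval.

    Zero cells get the 0.5 continuity correction with a warning; a zero
    margin leaves the odds ratio undefined.
    """
    arr = table.array()
    if arr.shape != (2, 2):
        raise ValueError("odds ratio requires a 2x2 table")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0,1)")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise UndefinedOddsRatioError("a zero margin makes the odds ratio undefined")
    if (arr == 0).any():
        logger.warning("zero cell(s): applying the 0.5 continuity correction")
        arr = arr + 0.5
    a, b, c, d = arr.ravel()
    or_ = (a * d) / (b * c)
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    half = z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(or_), float(or_ * math.exp(-half)), float(or_ * math.exp(half))


# ---------------------------------------------------------------------------
# result serialization

def association_results_frame(rows: list[dict]) -> pd.DataFrame:
    """Normalize association outputs into the documented TSV layout."""
    cols = ["statistic", "value", "p", "ci_lo", "ci_hi", "method", "seed"]
    return pd.DataFrame(rows).reindex(columns=cols)
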