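"""Seeded synthetic-cohort generator.

Emulates the statistical structure of an extreme-design watchful-waiting
expression cohort: two outcome classes (lethal / indolent), a minority of
outcome-associated genes, latent molecular subtypes within the lethal
class (inter-tumor heterogeneity: each subtype expresses its own disjoint
block of signal genes, so class-level signal dilutes as the subtype count
K grows), an ERG-rearranged subgroup enriched for lethality with its own
expression signature, stroma-contaminated samples carrying a fixed stroma
profile, and clinical covariates (age, grouped Gleason score) with a
tunable association to outcome.

The noise model is additive Gaussian on the log scale.  Baseline per-gene
means are drawn once per cohort, shared by all samples, mimicking the
gene-to-gene spread of log-intensity data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import (
    CohortDataset,
    ExpressionMatrix,
    PhenotypeTable,
    PHENOTYPE_COLUMNS,
)


class ConfigurationError(ValueError):
    """A simulation configuration is internally inconsistent."""


# per-class conditional Gleason distributions P(gleason | outcome), rows sum
# to 1; defaults chosen to yield a strong Gleason-outcome association of the
# kind observed in watchful-waiting cohorts (Cramer's V near 0.45)
DEFAULT_GLEASON_TABLE: Mapping[str, tuple[float, float, float]] = {
    "lethal": (0.20, 0.45, 0.35),   # G4_6, G7, G8_10
    "indolent": (0.52, 0.45, 0.03),
}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults reproduce the study-design shape
    (281 samples: 165 lethal / 116 indolent; 6100 genes)."""

    n_lethal: int = 165
    n_indolent: int = 116
    n_genes: int = 6100
    n_signal_genes: int = 100
    effect_size_delta: float = 1.0   # mean log-expression shift in lethal class
    noise_sd: float = 1.0            # per-gene Gaussian sd
    n_lethal_subtypes: int = 1       # K; disjoint signal-gene block per subtype
    erg_fraction: float = 0.16
    erg_target_odds_ratio: float = 7.2
    n_erg_signature_genes: int = 87
    erg_effect_size: float = 1.0
    stroma_fraction: float = 0.06
    n_stroma_genes: int = 47
    stroma_shift: float = 2.0
    gleason_outcome_table: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GLEASON_TABLE)
    )
    age_mean: float = 74.0
    age_sd: float = 6.0
    age_bounds: tuple[float, float] = (50.0, 95.0)
    survival_median_years: float = 5.0      # lognormal median of lethal death times
    survival_log_sd: float = 0.6
    indolent_followup_range: tuple[float, float] = (10.0, 25.0)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_lethal=self.n_lethal, n_indolent=self.n_indolent,
            n_genes=self.n_genes, n_signal_genes=self.n_signal_genes,
            n_lethal_subtypes=self.n_lethal_subtypes,
            n_erg_signature_genes=self.n_erg_signature_genes,
            n_stroma_genes=self.n_stroma_genes,
        )
        for name, v in counts.items():
            if v < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {v}")
        if self.n_lethal_subtypes < 1:
            raise ConfigurationError("n_lethal_subtypes must be >= 1")
        total_blocks = (
            self.n_signal_genes + self.n_erg_signature_genes + self.n_stroma_genes
        )
        if total_blocks > self.n_genes:
            raise ConfigurationError(
                f"gene blocks ({total_blocks}) exceed n_genes ({self.n_genes})"
            )
        for name, p in (("erg_fraction", self.erg_fraction),
                        ("stroma_fraction", self.stroma_fraction)):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {p}")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.erg_target_odds_ratio <= 0:
            raise ConfigurationError("erg_target_odds_ratio must be positive")
        for outcome in ("lethal", "indolent"):
            probs = self.gleason_outcome_table[outcome]
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ConfigurationError("gleason table rows need 3 non-negative probs")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"gleason probabilities for {outcome} sum to {sum(probs)}, not 1"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gleason_outcome_table"] = {k: list(v) for k, v in d["gleason_outcome_table"].items()}
        return d


@dataclass
class GroundTruth:
    """Latent structure of a generated cohort, for oracle-based tests."""

    signal_gene_ids: list[list[str]]          # one block per lethal subtype
    erg_signature_gene_ids: list[str]
    stroma_gene_ids: list[str]
    subtype_labels: pd.Series                 # per lethal sample, 1..K
    stroma_flags: pd.Series                   # per sample, bool
    erg_class_probs: tuple[float, float]      # P(ERG+|lethal), P(ERG+|indolent)


def solve_erg_probs(
    n_lethal: int, n_indolent: int, erg_fraction: float, target_or: float
) -> tuple[float, float]:
    """Per-class ERG+ probabilities matching an overall ERG fraction and a
    target lethal-vs-indolent odds ratio.

    With p1 = P(ERG+ | lethal) and p0 = P(ERG+ | indolent), the odds-ratio
    constraint gives p1 = OR*p0 / (1 + (OR-1)*p0); the marginal constraint
    is solved for p0 by bracketing (the marginal is monotone in p0).
    """
    if erg_fraction == 0.0:
        return 0.0, 0.0
    n = n_lethal + n_indolent

    def p1_of(p0: float) -> float:
        return target_or * p0 / (1.0 + (target_or - 1.0) * p0)

    def marginal(p0: float) -> float:
        return (n_lethal * p1_of(p0) + n_indolent * p0) / n - erg_fraction

    lo, hi = 1e-12, 1.0 - 1e-12
    if marginal(lo) > 0 or marginal(hi) < 0:
        raise ConfigurationError(
            f"erg_fraction={erg_fraction} infeasible for odds ratio {target_or}; "
            f"feasible marginal range is ({marginal(lo) + erg_fraction:.3g}, "
            f"{marginal(hi) + erg_fraction:.3g})"
        )
    p0 = float(brentq(marginal, lo, hi, xtol=1e-12))
    return p1_of(p0), p0


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():  # resample out-of-range draws; bounds are ~4 sd out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(config: SimulationConfig) -> tuple[CohortDataset, GroundTruth]:
    """Generate one cohort; deterministic given ``config.seed``."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_expr, rng_pheno, rng_struct = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    n_l, n_i = config.n_lethal, config.n_indolent
    n = n_l + n_i
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    outcome = np.array(["lethal"] * n_l + ["indolent"] * n_i)

    # disjoint gene blocks, laid out from the front of the gene list
    k = config.n_lethal_subtypes
    per_block = config.n_signal_genes // k
    blocks: list[list[str]] = []
    cursor = 0
    for b in range(k):
        size = per_block + (1 if b < config.n_signal_genes % k else 0)
        blocks.append(gene_ids[cursor:cursor + size])
        cursor += size
    erg_genes = gene_ids[cursor:cursor + config.n_erg_signature_genes]
    cursor += config.n_erg_signature_genes
    stroma_genes = gene_ids[cursor:cursor + config.n_stroma_genes]

    baseline = rng_expr.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    values = baseline[:, None] + rng_expr.normal(
        0.0, config.noise_sd, (config.n_genes, n)
    )

    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # lethal subtypes: uniform assignment; each subtype's block shifted
    subtype = rng_struct.integers(1, k + 1, size=n_l)
    for b, block in enumerate(blocks, start=1):
        if not block:
            continue
        rows = [gene_index[g] for g in block]
        cols = np.flatnonzero(subtype == b)  # lethal samples occupy columns 0..n_l-1
        if cols.size:
            values[np.ix_(rows, cols)] += config.effect_size_delta

    # ERG status: per-class Bernoulli with probabilities solved from the
    # marginal fraction and the target odds ratio
    p1, p0 = solve_erg_probs(n_l, n_i, config.erg_fraction, config.erg_target_odds_ratio)
    erg_pos = np.concatenate([
        rng_struct.random(n_l) < p1,
        rng_struct.random(n_i) < p0,
    ])
    if erg_genes and erg_pos.any():
        rows = [gene_index[g] for g in erg_genes]
        values[np.ix_(rows, np.flatnonzero(erg_pos))] += config.erg_effect_size

    # stroma contamination: a fixed per-cohort profile over the stroma genes
    # (offsets ~ N(shift, shift^2)); a constant shift would be invisible to
    # correlation distance, a patterned profile is what real contamination
    # looks like
    stroma_flag = rng_struct.random(n) < config.stroma_fraction
    if stroma_genes and stroma_flag.any():
        rows = [gene_index[g] for g in stroma_genes]
        profile = rng_struct.normal(
            config.stroma_shift, config.stroma_shift, len(stroma_genes)
        )
        values[np.ix_(rows, np.flatnonzero(stroma_flag))] += profile[:, None]

    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids))

    # clinical covariates and follow-up consistent with the outcome labels
    age = _truncated_normal(
        rng_pheno, config.age_mean, config.age_sd, *config.age_bounds, size=n
    )
    gleason_levels = np.array(["G4_6", "G7", "G8_10"])
    gleason = np.empty(n, dtype=object)
    for oc in ("lethal", "indolent"):
        mask = outcome == oc
        probs = np.asarray(config.gleason_outcome_table[oc], dtype=float)
        gleason[mask] = rng_pheno.choice(gleason_levels, size=int(mask.sum()), p=probs)
    mu = np.log(config.survival_median_years)
    death_times = rng_pheno.lognormal(mu, config.survival_log_sd, n_l)
    indolent_fup = rng_pheno.uniform(*config.indolent_followup_range, n_i)
    followup = np.concatenate([death_times, indolent_fup])

    pheno = PhenotypeTable(pd.DataFrame({
        "sample_id": sample_ids,
        "outcome": outcome,
        "death_from_cancer": outcome == "lethal",
        "followup_years": followup,
        "age_at_diagnosis": age,
        "gleason_category": gleason,
        "erg_status": np.where(erg_pos, "rearranged", "negative"),
    }, columns=list(PHENOTYPE_COLUMNS)))

    truth = GroundTruth(
        signal_gene_ids=blocks,
        erg_signature_gene_ids=list(erg_genes),
        stroma_gene_ids=list(stroma_genes),
        subtype_labels=pd.Series(subtype, index=sample_ids[:n_l], name="subtype"),
        stroma_flags=pd.Series(stroma_flag, index=sample_ids, name="stroma"),
        erg_class_probs=(p1, p0),
    )
    return CohortDataset(expr, pheno), truth


def apply_extreme_definition(
    phenotype: PhenotypeTable,
    lethal_within_years: float | None = None,
    indolent_beyond_years: float = 10.0,
) -> PhenotypeTable:
    """Reassign outcomes under an extreme-case definition.

    lethal: died of cancer, and (if a bound is set) within
    ``lethal_within_years`` of diagnosis.  indolent: alive without
    progression beyond ``indolent_beyond_years``.  Everything else —
    deaths from other causes within the window, short follow-up, cancer
    deaths past a stringent bound — is excluded.
    """
    if indolent_beyond_years <= 0:
        raise ValueError("indolent_beyond_years must be positive")
    if lethal_within_years is not None and lethal_within_years <= 0:
        raise ValueError("lethal_within_years must be positive")
    df = phenotype.table.copy()
    dfc = df["death_from_cancer"].astype(bool).to_numpy()
    fup = df["followup_years"].to_numpy(dtype=float)
    lethal = dfc if lethal_within_years is None else dfc & (fup <= lethal_within_years)
    indolent = (~dfc) & (fup >= indolent_beyond_years)
    new = np.where(lethal, "lethal", np.where(indolent, "indolent", "excluded"))
    n_changed = int((new != df["outcome"].to_numpy()).sum())
    import logging
    logging.getLogger(__name__).info(
        "extreme definition: %d lethal, %d indolent, %d excluded (%d reassigned)",
        int(lethal.sum()), int(indolent.sum()), int((new == "excluded").sum()), n_changed,
    )
    df["outcome"] = new
    return PhenotypeTable(df)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Serialize ground truth as a TSV sidecar (one row per annotated item)."""
    rows = []
    for b, block in enumerate(truth.signal_gene_ids, start=1):
        rows += [("signal_gene", g, str(b)) for g in block]
    rows += [("erg_signature_gene", g, "") for g in truth.erg_signature_gene_ids]
    rows += [("stroma_gene", g, "") for g in truth.stroma_gene_ids]
    rows += [("lethal_subtype", s, str(v)) for s, v in truth.subtype_labels.items()]
    rows += [("stroma_sample", s, str(bool(v)).lower())
             for s, v in truth.stroma_flags.items() if v]
    pd.DataFrame(rows, columns=["kind", "id", "value"]).to_csv(path, sep="\t", index=False)
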