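import numpy as np
import pandas as pd
import pytest

from progsig import CohortDataset, PhenotypeTable, SimulationConfig, generate_cohort


def small_config(**overrides) -> SimulationConfig:
    """A fast cohort: 60 samples, 200 genes, no ERG/stroma structure unless
    a test asks for it."""
    base = dict(
        n_lethal=35, n_indolent=25, n_genes=200, n_signal_genes=20,
        effect_size_delta=1.5, n_erg_signature_genes=0, n_stroma_genes=0,
        erg_fraction=0.15, seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture
def small_null_cohort():
    return generate_cohort(small_config(effect_size_delta=0.0, seed=5))


def permute_outcomes(dataset: CohortDataset, seed: int) -> CohortDataset:
    """Label permutation: reassign whole phenotype records to a random
    permutation of the expression samples (keeps every per-row invariant)."""
    rng = np.random.default_rng(seed)
    df = dataset.phenotype.table.copy()
    df["sample_id"] = rng.permutation(df["sample_id"].to_numpy())
    pheno = PhenotypeTable(df)
    return CohortDataset(dataset.expression, pheno.subset(dataset.expression.sample_ids))
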