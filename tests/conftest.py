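import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from logitda import (
    ClinicalTable,
    ExpressionMatrix,
    SimulationConfig,
    Unit,
    counts_to_log2tpm1,
    simulate_cohorts,
)

FIXTURE_DIR = Path(__file__).parent / "fixtures" / "worked"


@pytest.fixture(scope="session")
def worked_files():
    return FIXTURE_DIR


@pytest.fixture(scope="session")
def worked_manifest():
    with open(FIXTURE_DIR / "manifest.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def small_sim():
    """Small cohort pair with signal and shift, shared across tests."""
    cfg = SimulationConfig(
        n_genes=300, n_train=80, n_test=60, n_informative=20, n_shifted=10,
        frac_informative_shifted=0.5, seed=1,
    )
    return simulate_cohorts(cfg)


@pytest.fixture(scope="session")
def small_sim_log2(small_sim):
    train = counts_to_log2tpm1(small_sim.train_counts, small_sim.gene_lengths)
    test = counts_to_log2tpm1(small_sim.test_counts, small_sim.gene_lengths)
    return train, test


def make_expr(values, genes=None, samples=None, unit=Unit.counts):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit)


def make_clinical(sample_ids, response, **cols):
    df = pd.DataFrame({"response": response, **cols}, index=pd.Index(sample_ids, name="sample_id"))
    return ClinicalTable(df)
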