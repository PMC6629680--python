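import numpy as np
import pandas as pd
import pytest

from cystomics import (
    CohortSpec,
    ModelSpec,
    fit_model,
    preprocess_pipeline,
    simulate_cohort,
)

GROUPS4 = ("SCN", "LGD", "HGD", "Cancer")


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(
        n_per_group={g: 6 for g in GROUPS4},
        m_molecules=24,
        sigma=0.4,
        q_cens=0.15,
        seed=101,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_pre(small_cohort):
    return preprocess_pipeline(
        small_cohort.concentrations, small_cohort.clinical, seed=102
    )


@pytest.fixture(scope="session")
def small_draws(small_cohort, small_pre):
    spec = ModelSpec(groups=GROUPS4)
    return fit_model(
        small_pre,
        small_cohort.clinical,
        spec=spec,
        n_draws=800,
        n_chains=2,
        warmup=300,
        seed=103,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, samples=None, classes=None, log_scale=False):
    """Small helper to build a ConcentrationMatrix from a 2-D array."""
    from cystomics import ConcentrationMatrix

    values = np.asarray(values, dtype=float)
    mols = [f"mol_{i:03d}" for i in range(values.shape[0])]
    if samples is None:
        samples = [f"s{j:03d}" for j in range(values.shape[1])]
    if classes is None:
        classes = ["TAG"] * values.shape[0]
    return ConcentrationMatrix(
        values=pd.DataFrame(values, index=mols, columns=samples),
        classes=pd.Series(classes, index=mols),
        log_scale=log_scale,
    )
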