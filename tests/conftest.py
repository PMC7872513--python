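import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from omiclocks import (
    CohortConfig,
    LayerSimConfig,
    simulate_cohort,
    simulate_omics_layer,
    simulate_telomere,
)

settings.register_profile(
    "default",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects and independent layer deviations."""
    cfg = CohortConfig(n=600, determinant_effects={}, shared_loadings={})
    return simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def small_layer(null_cohort):
    """A small complete marker panel (no batches, no censoring)."""
    cohort, truth = null_cohort
    cfg = LayerSimConfig(
        name="epigenetic",
        n_markers=120,
        n_informative=30,
        target_r2=0.6,
        n_batches=1,
        batch_sd=0.0,
        n_labs=1,
    )
    return simulate_omics_layer(cohort, truth, cfg, seed=12)


@pytest.fixture(scope="session")
def telomere_layer(null_cohort):
    cohort, truth = null_cohort
    return simulate_telomere(cohort, truth, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
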