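import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"s{i:03d}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=samples)


@pytest.fixture
def small_matrix(rng):
    return make_matrix(rng.normal(8.0, 1.0, size=(50, 10)))


@pytest.fixture
def null_cohort():
    """Pure-noise two-group cohort: no DE, no covariate structure."""
    from progmark.synthetic import SimConfig, simulate_cohort

    cfg = SimConfig(
        n_genes=500, frac_de=0.0, noise_sd=1.0,
        batch_shift_sd=0.0, age_effect_sd=0.0, gender_effect_sd=0.0,
        n_outliers=0, n_low_rin=0, seed=11,
    )
    matrix, sheet, truth = simulate_cohort(cfg)
    return matrix, sheet, truth
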