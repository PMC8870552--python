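import numpy as np
import pytest

from pwasforge import simulate_genotypes, simulate_proteome
from pwasforge.simdata import default_annotation


@pytest.fixture(scope="session")
def small_panel():
    """Two-population dosage panel with moderate differentiation."""
    g, truth = simulate_genotypes(
        {"POP1": 150, "POP2": 150}, n_loci=4, snps_per_locus=12,
        fst_target=0.1, ld_decay=0.6, seed=11,
    )
    return g, truth


@pytest.fixture(scope="session")
def small_study():
    """Panel + proteome + annotation for a single-population cohort."""
    g, truth = simulate_genotypes(
        {"TRAIN": 250}, n_loci=5, snps_per_locus=12,
        fst_target=0.0, ld_decay=0.6, seed=21,
    )
    ann = default_annotation(truth)
    raw, covariates, truth = simulate_proteome(
        g, ann, truth, n_causal=1, h2=0.6, n_timepoints=2, seed=22,
    )
    return g, truth, ann, raw, covariates


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
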