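import numpy as np
import pytest

from vqtlscan.containers import covariate_columns, covariate_design
from vqtlscan.simulate import TraitSpec, simulate_covariates, simulate_genotypes, simulate_trait


@pytest.fixture
def small_cohort():
    """n=5000 cohort with one mean-effect variant and one variance-effect variant."""
    gm = simulate_genotypes(5000, [0.3, 0.2, 0.4], seed=11)
    cov = simulate_covariates(5000, seed=12, n_pcs=5)
    spec = TraitSpec(
        beta_mean={"v0": 0.15},
        gamma_var={"v1": 0.4},
        covariate_effects={"sex": 0.2, "PC1": 0.1},
    )
    ph = simulate_trait(gm, cov, spec, seed=13)
    X = covariate_design(ph, covariate_columns(5))
    return gm, ph, X, spec
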