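import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import edgenull as en

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def factor_model():
    """Dense 6-node correlation with a generic (non-degenerate) spectrum."""
    return en.build_correlation(
        en.CorrelationSpec(6, "random_factor", n_factors=2, seed=11)
    )


@pytest.fixture(scope="session")
def modular_model():
    """Two planted modules of unequal size (unique leading eigenvalue)."""
    return en.build_correlation(
        en.CorrelationSpec(20, "modular", module_sizes=(12, 8), rho_within=0.5)
    )


@pytest.fixture(scope="session")
def null_surrogate(factor_model):
    """A moderately long null surrogate matched to ``factor_model``."""
    spec = en.SurrogateSpec(correlation=factor_model, n_frames=20_000, seed=21)
    return en.zscore(en.sample_bold(spec))


def population_standardised(bold: en.BoldMatrix) -> en.BoldMatrix:
    """Treat a null surrogate as z-scored by construction.

    The null model draws frames from N(0, R) whose marginals are already
    standardised at the population level; skipping the sample z-score keeps
    the analytic RSS law exact (no variance pinning).
    """
    return en.BoldMatrix(bold.values, node_ids=bold.node_ids, zscored=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
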