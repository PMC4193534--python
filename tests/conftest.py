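import numpy as np
import pytest

from dualscreen import (
    MCMCConfig,
    ModelParams,
    colorectal_counts,
    colorectal_priors,
    fit,
)


def random_valid_params(rng: np.random.Generator, dependence: bool = True) -> ModelParams:
    """A parameter draw satisfying every ModelParams invariant."""
    pi, se1, se2, sp1, sp2 = rng.uniform(0.0, 1.0, size=5)
    if dependence:
        cdp = rng.uniform(0.0, min(se1, se2) - se1 * se2)
        cdn = rng.uniform(0.0, min(sp1, sp2) - sp1 * sp2)
    else:
        cdp = cdn = 0.0
    return ModelParams(pi=pi, se1=se1, se2=se2, sp1=sp1, sp2=sp2,
                       cov_dp=cdp, cov_dn=cdn)


@pytest.fixture(scope="session")
def colorectal_fit_full():
    """Full-length colorectal fit shared by the acceptance-level tests."""
    return fit(
        colorectal_counts(),
        colorectal_priors(),
        MCMCConfig(n_chains=2, n_iterations=105_000, n_burnin=5_000, seed=1234),
    )


@pytest.fixture(scope="session")
def colorectal_fit_short():
    """Cheap colorectal fit for unit-level checks of the battery."""
    return fit(
        colorectal_counts(),
        colorectal_priors(),
        MCMCConfig(n_chains=2, n_iterations=8_000, n_burnin=1_000, seed=7),
    )
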