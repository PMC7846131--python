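import numpy as np
import pytest

import funcfdr as F


@pytest.fixture(scope="session")
def uniform_dataset_20k():
    """20000 tests with p and covariate independent Uniform(0,1): pure null,
    uninformative covariate, true joint density identically 1."""
    rng = np.random.default_rng(3)
    return F.Dataset.from_arrays(
        p=rng.uniform(size=20000), z_raw=rng.uniform(size=20000)
    )


@pytest.fixture(scope="session")
def uniform_density_fit(uniform_dataset_20k):
    return F.estimate_joint_density(uniform_dataset_20k, seed=3)


def _study(pi0_spec, seed):
    cfg = F.SimulationConfig(
        m=3000, pi0_spec=pi0_spec, alt_spec="beta:a=0.25", seed=seed
    )
    return F.run_simulation_study(
        cfg, replicates=100, alpha=0.05, pi0_method="glm", lam=0.5
    )


@pytest.fixture(scope="session")
def informative_study():
    """100 replicates of the informative-Z design pi0(z) = 0.6 + 0.3 z."""
    return _study("linear:c0=0.6,c1=0.3", seed=2000)


@pytest.fixture(scope="session")
def noninformative_study():
    """100 replicates with constant pi0 and a z-free alternative."""
    return _study("constant:c=0.75", seed=4000)
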