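import numpy as np
import pandas as pd
import pytest

from ctiva.opt_density import PiecewiseDensity, fit_joint
from ctiva.simulate import SimConfig, make_replicate


@pytest.fixture
def uniform_unit_density() -> PiecewiseDensity:
    """Uniform density on the unit square, 8x8 dyadic grid."""
    e = np.linspace(0.0, 1.0, 9)
    return PiecewiseDensity(e, e, np.full((8, 8), 1.0 / 64.0))


@pytest.fixture(scope="session")
def default_replicate():
    """One default additive-exponential replicate (n=500, 1000 categorical
    covariates, ~35% censoring)."""
    return make_replicate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_fit(default_replicate):
    """Joint density fitted on the default replicate (shared: fitting is the
    expensive step)."""
    return fit_joint(default_replicate.observations, max_depth=8, max_iter=10,
                     tol=1e-3)


@pytest.fixture(scope="session")
def uncensored_obs():
    """A small fully observed dataset (no censoring at all)."""
    rng = np.random.default_rng(42)
    t1 = rng.exponential(size=60)
    t2 = t1 + rng.exponential(size=60)
    return pd.DataFrame({"v1": t1, "delta1": 1, "v2": t2, "delta2": 1})
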