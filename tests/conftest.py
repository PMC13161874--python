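import numpy as np
import pandas as pd
import pytest

from strokeconn.atlas import default_atlas
from strokeconn.simulate import SimulationConfig, generate_cohort

#: small pseudo-region set used by scaled-down network studies
REGIONS6 = ["L.a", "L.b", "L.c", "R.a", "R.b", "R.c"]


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def cohort20():
    return generate_cohort(20, seed=11)


@pytest.fixture(scope="session")
def cohort49():
    return generate_cohort(49, seed=12)


@pytest.fixture()
def small_config():
    return SimulationConfig(n_subjects=20, baseline_log_rate=0.0, seed=13)


@pytest.fixture(scope="session")
def links_small(atlas):
    cohort = generate_cohort(8, seed=21)
    from strokeconn.simulate import simulate_patch_links

    cfg = SimulationConfig(n_subjects=8, seed=22)
    return cohort, simulate_patch_links(cohort, cfg, [], atlas)


def make_zip_glmm_data(
    rng, n_subjects=50, n_trials=4, intercept=np.log(3), slope=0.08,
    sigma_u=0.3, pi=0.2, x_sd=3.0,
):
    """Draw one dataset from the ZIP random-intercept model itself."""
    x = rng.normal(0, x_sd, n_subjects)
    u = rng.normal(0, sigma_u, n_subjects)
    lam = np.exp(intercept + slope * x + u)
    y = rng.poisson(np.repeat(lam, n_trials))
    y[rng.random(n_subjects * n_trials) < pi] = 0
    return pd.DataFrame(
        {
            "subject": np.repeat([f"s{i:03d}" for i in range(n_subjects)], n_trials),
            "x": np.repeat(x, n_trials),
            "count": y,
        }
    )
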