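import numpy as np
import pytest

from streamtemp.model import ModelParams, build_design
from streamtemp.sampler import MCMCConfig, sample_posterior
from streamtemp.synthetic import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def tiny_cfg():
    """2 sites x 3 years, no missingness: the smallest realistic dataset."""
    return SyntheticConfig(sites=("WB", "OL"), years=(2001, 2002, 2003), seed=42)


@pytest.fixture(scope="session")
def tiny_sim(tiny_cfg):
    df, truth = simulate(tiny_cfg)
    return df, truth


@pytest.fixture(scope="session")
def tiny_design(tiny_cfg, tiny_sim):
    df, truth = tiny_sim
    return build_design(
        df, truth.windows_frame(), std=truth.std, sites=tiny_cfg.sites, observed_only=False
    )


@pytest.fixture(scope="session")
def tiny_posterior(tiny_design):
    mcmc = MCMCConfig(n_chains=2, burn_in=200, iterations=200, thin=1)
    return sample_posterior(tiny_design, mcmc, seed=11)


def random_params(rng, n_sites, years):
    """A random interior parameter point (for density oracles)."""
    A = rng.normal(0, 0.4, (4, 4))
    Sigma = A @ A.T + 0.3 * np.eye(4)
    M = np.concatenate([[0.0], rng.normal(0, 1, 3)])
    return ModelParams(
        alpha=rng.normal(10, 3),
        beta=rng.normal(0, 1, 11),
        B=rng.normal(0, 1, (len(years), 4)),
        b_years=tuple(years),
        M=M,
        Sigma=Sigma,
        delta=rng.uniform(-0.9, 0.9, n_sites),
        mu_delta=rng.uniform(-0.8, 0.8),
        sd_delta=rng.uniform(0.05, 1.5),
        sd=rng.uniform(0.3, 3.0),
    )
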