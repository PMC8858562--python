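import numpy as np
import pytest

import srbtrans as st


@pytest.fixture(scope="session")
def small_scenario() -> st.ScenarioConfig:
    """Three-province scenario small enough for repeated MCMC in tests."""
    return st.ScenarioConfig(
        n_provinces=3,
        deltas=(1, 0, 1),
        shapes=(
            st.TransitionShape(2000.0, 10.0, 12.0, 13.0, 0.08),
            st.TransitionShape(2005.0, 10.0, 12.0, 13.0, 0.0),
            st.TransitionShape(1998.0, 11.0, 12.0, 13.0, 0.07),
        ),
        births_per_obs=3000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario) -> st.SyntheticDataset:
    return st.simulate_dataset(small_scenario)


@pytest.fixture(scope="session")
def small_fit(small_dataset) -> st.PosteriorSamples:
    """One modest posterior fit shared by read-only summary/projection tests."""
    mc = st.MCMCConfig(n_chains=2, n_warmup=300, n_samples=600, seed=21)
    return st.fit_mcmc(small_dataset.observations, small_dataset.tfr,
                       st.ModelConfig(), mc)


def make_posterior(delta, t0, len_increase, len_stagnation, len_decrease,
                   max_inflation, phi=None, years=None,
                   model_config=None) -> st.PosteriorSamples:
    """Hand-built PosteriorSamples with draws along axis 0 of each input.

    Inputs are (n_draws, P) arrays (phi: (n_draws, P, T)); a single chain is
    assumed. Useful for exercising summaries against known draws.
    """
    delta = np.asarray(delta)
    n, P = delta.shape
    cfg = model_config or st.ModelConfig()
    if years is None:
        years = cfg.years
    years = np.asarray(years)
    if phi is None:
        phi = np.ones((n, P, len(years)))

    def _c(a):
        return np.asarray(a, dtype=float)[None, ...]

    return st.PosteriorSamples(
        provinces=tuple(f"Province {i + 1}" for i in range(P)),
        years=years,
        phi=_c(phi),
        delta=np.asarray(delta)[None, ...].astype(int),
        pi=_c(np.full((n, P), 0.5)),
        t0=_c(t0), len_increase=_c(len_increase),
        len_stagnation=_c(len_stagnation), len_decrease=_c(len_decrease),
        max_inflation=_c(max_inflation),
        hypers=_c(np.tile(st.HierarchicalHypers().as_array(), (n, 1))),
        model_config=cfg,
        mcmc_config=st.MCMCConfig(n_chains=1, n_warmup=1, n_samples=n),
    )
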