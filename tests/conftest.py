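import numpy as np
import pandas as pd
import pytest

import secr1d as s


@pytest.fixture(scope="session")
def small_scenario():
    return s.SimScenario(n_bins=20, n_years=2, n_individuals=8,
                         n_days_per_year=20, seed=123)


@pytest.fixture(scope="session")
def small_data(small_scenario):
    scen = small_scenario
    effort = s.simulate_effort(scen)
    truth = s.simulate_individuals(scen)
    sightings = s.simulate_sightings(truth, effort, scen)
    return {"scenario": scen, "effort": effort, "truth": truth,
            "sightings": sightings, "grid": scen.grid}


@pytest.fixture(scope="session")
def small_encounters(small_data):
    binned = s.assign_latitude_bins(small_data["sightings"], small_data["grid"])
    return s.build_encounter_array(binned, small_data["effort"],
                                   small_data["grid"], min_days=5)


@pytest.fixture(scope="session")
def small_fit(small_encounters, small_data):
    cfg = s.ModelConfig(n_chains=2, n_iter=4000, burn_in=1000, thin=5, seed=9)
    return s.mcmc_fit(small_encounters, small_data["grid"], cfg)


def make_samples(C, sigma2, R, A, individuals=None, years=None,
                 mu=None, omega=None, beta_e=None):
    """Build a PosteriorSamples directly from per-draw arrays.

    C, sigma2, R, A: arrays of shape (n_draws, n_ind, n_years); a single
    chain is assumed. Used to feed hand-constructed posteriors into the
    space-use, exposure and post hoc operations.
    """
    C = np.asarray(C, float)[None]
    sigma2 = np.asarray(sigma2, float)[None]
    R = np.asarray(R, float)[None]
    A = np.asarray(A, int)[None]
    n_draws, I, T = C.shape[1:]
    individuals = individuals or [f"ind{i}" for i in range(I)]
    years = years or list(range(2016, 2016 + T))
    z = np.zeros((1, n_draws))
    params = {"C": C, "sigma2": sigma2, "R": R, "A": A, "M": np.zeros_like(C),
              "mu": z if mu is None else np.full((1, n_draws), mu),
              "omega": z + 1 if omega is None else np.full((1, n_draws), omega),
              "beta_e": z if beta_e is None else np.full((1, n_draws), beta_e)}
    cfg = s.ModelConfig(n_chains=1, n_iter=max(2, n_draws + 1), burn_in=1,
                        thin=1, seed=0)
    return s.PosteriorSamples(params=params, individuals=individuals,
                              years=years, config=cfg)
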