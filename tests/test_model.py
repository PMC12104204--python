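import numpy as np
import pytest

import secr1d as s
from secr1d.encounters import EncounterArray

from .oracles import brute_force_loglik


def random_instance(rng, I=3, L=6, T=2):
    e = rng.uniform(0, 5, size=(L, T))
    e[rng.random((L, T)) < 0.2] = 0.0
    if e.max() == 0:
        e[0, 0] = 1.0
    S = rng.poisson(1.0, size=(I, L, T))
    S[:, e == 0] = 0
    A = rng.binomial(1, 0.7, size=(I, T))
    # a positive count forces presence; clear counts where absent
    S *= A[:, None, :]
    grid = s.LatitudeGrid(44.0, 0.01, L)
    lo, hi = grid.extent
    state = {
        "C": rng.uniform(lo, hi, size=(I, T)),
        "sigma2": np.exp(rng.normal(-5.5, 1.0, size=(I, T))),
        "R": rng.normal(0, 1, size=(I, T)),
        "A": A,
        "beta_e": rng.normal(0, 0.3),
    }
    enc = EncounterArray(S=S, e=e, survey_days=np.full((I, T), 5),
                         included=np.ones((I, T), bool),
                         individuals=[f"i{k}" for k in range(I)],
                         years=list(range(2016, 2016 + T)))
    return enc, grid, state


class TestScaleEffort:
    def test_linear_scaling(self):
        np.testing.assert_allclose(s.scale_effort(np.array([0.0, 50.0, 100.0])),
                                   [0.0, 5.0, 10.0])

    def test_max_is_ten_and_constant_case(self):
        rng = np.random.default_rng(1)
        e = rng.uniform(0, 7, size=(5, 3))
        assert s.scale_effort(e).max() == pytest.approx(10.0)
        np.testing.assert_allclose(s.scale_effort(np.full(4, 2.5)), 10.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            s.scale_effort(np.zeros(3))


class TestExpectedRate:
    def test_zero_effort_means_zero_rate(self):
        assert s.expected_rate(44.0, 0.01, 0.5, 1, 0.2, 0.0, 44.05) == 0.0

    def test_identity_case(self):
        # at the center with unit baseline the rate is exactly 1
        assert s.expected_rate(44.05, 0.01, 0.0, 1, 0.0, 3.0, 44.05) == pytest.approx(1.0)

    def test_half_normal_kernel_at_one_sigma(self):
        sigma2 = 0.004
        d = np.sqrt(sigma2)
        lam = s.expected_rate(44.0 + d, sigma2, 0.0, 1, 0.0, 3.0, 44.0)
        assert lam == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_monotone_in_distance(self):
        ds = np.linspace(0, 0.3, 50)
        lams = s.expected_rate(44.0 + ds, 0.003, 0.4, 1, 0.1, 5.0, 44.0)
        assert np.all(np.diff(lams) <= 0)

    def test_nonpositive_sigma2_rejected(self):
        with pytest.raises(ValueError):
            s.expected_rate(44.0, 0.0, 0.0, 1, 0.0, 3.0, 44.0)


class TestLogLikelihood:
    def test_all_zero_counts_all_absent_is_zero(self):
        rng = np.random.default_rng(0)
        enc, grid, state = random_instance(rng)
        enc.S[:] = 0
        state["A"] = np.zeros_like(state["A"])
        assert s.log_likelihood(enc, state, grid) == 0.0

    def test_single_cell_poisson_pmf(self):
        # S = 2 at lambda = 1: log pmf = -1 - log 2
        grid = s.LatitudeGrid(44.0, 0.01, 2)
        enc = EncounterArray(S=np.array([[[2], [0]]]),
                             e=np.array([[1.0], [0.0]]),
                             survey_days=np.array([[5]]),
                             included=np.array([[True]]),
                             individuals=["a"], years=[2020])
        state = {"C": np.array([[grid.centroids[0]]]),
                 "sigma2": np.array([[1.0]]),
                 "R": np.array([[0.0]]), "A": np.array([[1]]), "beta_e": 0.0}
        # gamma = exp(0) = 1 and d = 0, so lambda = 1 in the surveyed bin
        assert s.log_likelihood(enc, state, grid) == pytest.approx(-1 - np.log(2))

    def test_absent_with_sightings_is_impossible(self):
        rng = np.random.default_rng(3)
        enc, grid, state = random_instance(rng)
        i, t = np.argwhere(enc.S.sum(axis=1) > 0)[0]
        state["A"] = state["A"].copy()
        state["A"][i, t] = 0
        assert s.log_likelihood(enc, state, grid) == -np.inf

    def test_matches_brute_force_oracle(self):
        # vectorised implementation vs naive triple loop on random instances
        rng = np.random.default_rng(42)
        for _ in range(100):
            enc, grid, state = random_instance(rng)
            got = s.log_likelihood(enc, state, grid)
            want = brute_force_loglik(enc.S, enc.e, grid.centroids,
                                      state["C"], state["sigma2"], state["R"],
                                      state["A"], state["beta_e"])
            if np.isinf(want):
                assert np.isinf(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)


class TestMcmcBehaviour:
    def test_presence_forced_by_sightings(self, small_fit, small_encounters):
        A = small_fit.flat("A")
        any_S = small_encounters.S.sum(axis=1) > 0
        assert np.all(A[:, any_S] == 1)

    def test_absent_draws_are_pinned(self, small_fit):
        A = small_fit.flat("A")
        C = small_fit.flat("C")
        s2 = small_fit.flat("sigma2")
        absent = A == 0
        assert absent.any()
        assert np.all(C[absent] == 52.0)
        assert np.all(s2[absent] == 0.001)

    def test_zero_information_presence_matches_prior(self):
        # one individual never sighted: posterior Pr(A=1) must stay at 0.5
        grid = s.LatitudeGrid(44.0, 0.01, 5)
        enc = EncounterArray(S=np.zeros((1, 5, 1), int),
                             e=np.full((5, 1), 2.0),
                             survey_days=np.zeros((1, 1), int),
                             included=np.zeros((1, 1), bool),
                             individuals=["ghost"], years=[2020])
        # pin the latent kernel so lambda ~ 0 and the likelihood carries no
        # information about presence
        cfg = s.ModelConfig(n_chains=1, n_iter=30_000, burn_in=2_000, thin=1,
                            seed=5, fixed={"mu": -18.0, "M": 0.0, "R": -8.0,
                                           "beta_e": 0.0, "omega": 1.0})
        post = s.mcmc_fit(enc, grid, cfg)
        p_present = post.flat("A").mean()
        assert abs(p_present - 0.5) < 0.02

    def test_draw_count_contract(self, small_fit):
        cfg = small_fit.config
        assert small_fit.n_draws == (cfg.n_iter - cfg.burn_in) // cfg.thin
        for name in ("C", "sigma2", "R", "A", "mu", "omega", "beta_e"):
            assert np.all(np.isfinite(small_fit.flat(name)))

    def test_chains_differ_only_by_seed_stream(self, small_encounters, small_data):
        cfg = s.ModelConfig(n_chains=2, n_iter=400, burn_in=100, thin=5, seed=77)
        a = s.mcmc_fit(small_encounters, small_data["grid"], cfg)
        b = s.mcmc_fit(small_encounters, small_data["grid"], cfg)
        np.testing.assert_array_equal(a.params["C"], b.params["C"])
        assert not np.array_equal(a.params["C"][0], a.params["C"][1])

    def test_prior_recovery_with_no_individuals(self):
        # empty data: the sampler must reproduce the priors of the globals
        from scipy.stats import kstest, halfnorm, norm
        grid = s.LatitudeGrid(44.0, 0.01, 4)
        enc = EncounterArray(S=np.zeros((0, 4, 1), int), e=np.full((4, 1), 1.0),
                             survey_days=np.zeros((0, 1), int),
                             included=np.zeros((0, 1), bool),
                             individuals=[], years=[2020])
        cfg = s.ModelConfig(n_chains=1, n_iter=62_000, burn_in=2_000, thin=4,
                            seed=11)
        post = s.mcmc_fit(enc, grid, cfg)
        pri = cfg.priors
        assert kstest(post.flat("mu"), norm(pri.mu_mean, pri.mu_sd).cdf).statistic < 0.05
        assert kstest(post.flat("omega"), halfnorm(scale=pri.omega_scale).cdf).statistic < 0.05
        assert kstest(post.flat("beta_e"), norm(pri.beta_e_mean, pri.beta_e_sd).cdf).statistic < 0.05

    def test_config_validation(self):
        with pytest.raises(ValueError):
            s.ModelConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            s.ModelConfig(fixed={"sigma_prior_typo": 1.0})
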