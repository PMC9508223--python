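import numpy as np
import pandas as pd
import pytest

from celltraffic.mcmc import (
    ChainSet,
    GaussianLogPrior,
    McmcOptions,
    log_likelihood,
    posterior_summary,
    rhat,
    run_mcmc,
    sample_adaptive_chains,
)
from celltraffic.datasets import LocalisationDataset
from celltraffic.kinetics import KineticParameters
from celltraffic.synthetic import (
    NoiseConfig,
    add_noise,
    default_truth,
    make_dataset,
    reduced_system,
)


class TestLogLikelihood:
    def _one_point_dataset(self, value):
        return LocalisationDataset(
            pd.DataFrame({"curve": ["Muscle"], "time_h": [1.0], "value": [value]})
        )

    def test_exact_match_leaves_normalisation_term(
        self, single_organ_system, single_organ_params
    ):
        from celltraffic.fitting import ScoreEngine

        model = ScoreEngine(
            single_organ_system,
            self._one_point_dataset(0.5),
        )
        m = float(model.model_matrix(single_organ_params)[0, -1])
        ds = self._one_point_dataset(m)
        sigma = 0.1
        ll = log_likelihood(single_organ_system, single_organ_params, ds, sigma)
        expected = -np.log(np.sqrt(2 * np.pi) * sigma * m)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_one_point_closed_form(self, single_organ_system, single_organ_params):
        """Datum 2, model output shifted 0.2 away, sigma 0.1: the Gaussian
        (mean 2, sd 0.2) log-density at the model value."""
        from celltraffic.fitting import ScoreEngine
        from scipy.stats import norm

        engine = ScoreEngine(single_organ_system, self._one_point_dataset(1.0))
        m = float(engine.model_matrix(single_organ_params)[0, -1])
        d = m - 0.2  # datum such that model = datum + 0.2
        scale_d = 2.0 / d  # rescale datum to exactly 2 via dose linearity
        ds = self._one_point_dataset(d)
        ll = log_likelihood(single_organ_system, single_organ_params, ds, 0.1)
        expected = norm.logpdf(m, loc=d, scale=0.1 * d)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_larger_residual_lowers_likelihood(
        self, rat_system, truth, noise_free_dataset
    ):
        noisy = add_noise(noise_free_dataset, NoiseConfig(0.1, seed=2))
        base = log_likelihood(rat_system, truth, noisy, 0.1)
        worse = KineticParameters(
            rat_system.names, np.clip(truth.e * 1.5, 0, 1), truth.mu
        )
        assert log_likelihood(rat_system, worse, noisy, 0.1) < base

    def test_nonpositive_sigma_rejected(self, rat_system, truth, noise_free_dataset):
        with pytest.raises(ValueError):
            log_likelihood(rat_system, truth, noise_free_dataset, 0.0)

    def test_zero_data_points_excluded(self, rat_system, truth, noise_free_dataset):
        """t = 0 organ rows carry no proportional-noise information."""
        from celltraffic.mcmc import _Likelihood

        lik = _Likelihood(rat_system, noise_free_dataset)
        assert lik.n_excluded_zeros == 7  # every organ curve's initial row
        assert np.isfinite(lik(truth, 0.1))


class TestRhat:
    def test_identical_chains_with_internal_variance(self):
        c = np.sin(np.arange(100.0))
        n = len(c)
        assert rhat([c, c.copy(), c.copy()]) == pytest.approx(
            np.sqrt((n - 1) / n)
        )

    def test_same_gaussian_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = [rng.normal(size=10_000) for _ in range(3)]
        assert 0.99 <= rhat(chains) <= 1.01

    def test_separated_chains_exceed_threshold(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 2_000)
        b = rng.normal(10.0, 1.0, 2_000)
        assert rhat([a, b]) > 1.1

    def test_frozen_distinct_chains_flagged_infinite(self):
        assert rhat([np.zeros(10), np.ones(10)]) == np.inf


class TestSampler:
    def test_standard_gaussian_oracle(self):
        """Known-distribution check: mean and sd recovered within 0.05."""
        cs = sample_adaptive_chains(
            lambda x: -0.5 * float(x @ x),
            [np.full(2, s) for s in (-2.0, 0.0, 2.0)],
            McmcOptions(burn_in=500, cycle_length=5000, max_cycles=10, seed=3),
        )
        assert cs.converged
        pooled = np.concatenate([cs.post_burn(i) for i in range(3)])
        assert np.abs(pooled.mean(axis=0)).max() < 0.05
        assert np.abs(pooled.std(axis=0) - 1.0).max() < 0.05

    def test_correlated_gaussian_moments_within_5pct(self):
        """5-d correlated target: mean and covariance within 5%."""
        rng = np.random.default_rng(5)
        A = rng.normal(size=(5, 5))
        C = A @ A.T + 0.5 * np.eye(5)
        Ci = np.linalg.inv(C)
        cs = sample_adaptive_chains(
            lambda x: -0.5 * float(x @ Ci @ x),
            [rng.normal(size=5) for _ in range(3)],
            McmcOptions(
                burn_in=1000, cycle_length=5000, rhat_target=1.0001,
                max_cycles=20, seed=2,
            ),
        )
        pooled = np.concatenate([cs.post_burn(i) for i in range(3)])
        emp = np.cov(pooled.T)
        scale = np.abs(C).max()
        assert np.abs(emp - C).max() / scale < 0.05
        assert np.abs(pooled.mean(axis=0)).max() / np.sqrt(np.diag(C)).max() < 0.05

    def test_impossible_states_never_accepted(self):
        """Metropolis smoke test: -inf posterior proposals are rejected."""
        def half_line(x):
            return -0.5 * float(x @ x) if x[0] > 0 else -np.inf

        cs = sample_adaptive_chains(
            [half_line][0],
            [np.array([1.0]), np.array([2.0]), np.array([0.5])],
            McmcOptions(burn_in=200, cycle_length=1000, max_cycles=5, seed=4),
        )
        for i in range(3):
            assert (cs.chains[i][:, 0] > 0).all()

    def test_same_seed_gives_identical_chains(self, truth):
        system = reduced_system(
            organ_subset=["Stomach", "S.Intestine", "LymphNodes"]
        )
        params = default_truth(system, 0)
        ds = add_noise(make_dataset(system, params), NoiseConfig(0.1, seed=3))
        opts = McmcOptions(
            burn_in=100, cycle_length=300, max_cycles=2, seed=11
        )
        a = run_mcmc(system, ds, options=opts)
        b = run_mcmc(system, ds, options=opts)
        for ca, cb in zip(a.chains, b.chains):
            np.testing.assert_array_equal(ca, cb)


class TestPosteriorSummary:
    def _toy_chainset(self, chains, cycle_length=100):
        return ChainSet(
            param_names=["x0"],
            chains=[np.asarray(c)[:, None] for c in chains],
            log_posteriors=[np.zeros(len(c)) for c in chains],
            burn_in=0,
            cycle_length=cycle_length,
            n_cycles=1,
            rhat_history=[np.array([1.0])],
            acceptance_rates=[0.3] * len(chains),
            converged=True,
        )

    def test_identical_endpoints_zero_sd(self):
        chains = [np.full(100, 0.5) for _ in range(3)]
        summ = posterior_summary(self._toy_chainset(chains))
        assert summ.table.iloc[0].endpoint_sd == 0.0

    def test_uniform_prior_samples_classified_diffuse(self):
        rng = np.random.default_rng(0)
        chains = [rng.uniform(-3, 0, 5000) for _ in range(3)]
        summ = posterior_summary(self._toy_chainset(chains, cycle_length=5000))
        assert summ.table.iloc[0].density_shape in {"diffuse", "multimodal"}

    def test_tight_mode_classified_peaked(self):
        rng = np.random.default_rng(0)
        chains = [rng.normal(-1.0, 0.02, 5000) for _ in range(3)]
        summ = posterior_summary(self._toy_chainset(chains, cycle_length=5000))
        assert summ.table.iloc[0].density_shape == "peaked"

    def test_coverage_indicator(self):
        rng = np.random.default_rng(2)
        chains = [rng.normal(-1.0, 0.05, 1000) for _ in range(3)]
        cs = self._toy_chainset(chains, cycle_length=1000)
        truth = {"x0": 10.0 ** chains[0][-1]}
        summ = posterior_summary(cs, truth=truth)
        assert bool(summ.table.iloc[0].covered) in {True, False}
        assert "truth" in summ.table.columns
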