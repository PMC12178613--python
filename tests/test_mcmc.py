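"""Likelihood, Metropolis-Hastings sampler and posterior summaries."""

import math

import numpy as np
import pytest

from allokin import (
    KineticRecord,
    MCMCConfig,
    RecordSet,
    ScalingParams,
    km_distribution,
    log_likelihood,
    lognormal_logpdf,
    metropolis_hastings,
    moment_match_init,
    propose,
    summarize_posterior,
    vmaxdw_distribution,
)
from allokin.mcmc import log_likelihood_dense, metropolis_hastings_core


def _paired_recordset(vmax, km):
    return RecordSet(
        [
            KineticRecord(f"o{i}", "g", vmax_dw=float(v), km=float(k))
            for i, (v, k) in enumerate(zip(vmax, km))
        ]
    )


class TestLogLikelihood:
    def test_single_record_at_both_modes(self, posterior_mean_params, constants, prior):
        spec_v = vmaxdw_distribution(posterior_mean_params, constants, prior)
        spec_k = km_distribution(posterior_mean_params, constants, prior)
        rs = _paired_recordset([spec_v.mode], [spec_k.mode])
        expected = lognormal_logpdf(spec_v.mode, spec_v) + lognormal_logpdf(
            spec_k.mode, spec_k
        )
        got = log_likelihood(posterior_mean_params, rs, constants, prior)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_additivity_over_identical_records(
        self, posterior_mean_params, constants, prior
    ):
        one = _paired_recordset([2e-3], [3e-5])
        ten = _paired_recordset([2e-3] * 10, [3e-5] * 10)
        l1 = log_likelihood(posterior_mean_params, one, constants, prior)
        l10 = log_likelihood(posterior_mean_params, ten, constants, prior)
        assert l10 == pytest.approx(10 * l1, rel=1e-12)

    def test_degenerate_params_give_minus_inf(self, constants, prior):
        rs = _paired_recordset([1e-3], [1e-5])
        p = ScalingParams(a=1e-14, b=constants.beta, c_bar=1.0, d=1.0)
        assert log_likelihood(p, rs, constants, prior) == -math.inf

    def test_empty_data_is_an_error(self, posterior_mean_params, constants, prior):
        with pytest.raises(ValueError):
            log_likelihood(posterior_mean_params, RecordSet([]), constants, prior)

    def test_partial_records_contribute_one_term(
        self, posterior_mean_params, constants, prior
    ):
        spec_v = vmaxdw_distribution(posterior_mean_params, constants, prior)
        rs = RecordSet([KineticRecord("x", "g", vmax_dw=2e-3)])
        got = log_likelihood(posterior_mean_params, rs, constants, prior)
        assert got == pytest.approx(float(lognormal_logpdf(2e-3, spec_v)), rel=1e-12)

    def test_shuffle_invariance_of_factorised_likelihood(
        self, posterior_mean_params, constants, prior, synthetic_161
    ):
        """The likelihood factorises over the two variables, so pairing K_m
        values with different V_maxDW values cannot change it."""
        v, k = synthetic_161.paired_values()
        rng = np.random.default_rng(3)
        shuffled = _paired_recordset(v, rng.permutation(k))
        original = _paired_recordset(v, k)
        l0 = log_likelihood(posterior_mean_params, original, constants, prior)
        l1 = log_likelihood(posterior_mean_params, shuffled, constants, prior)
        assert l1 == pytest.approx(l0, rel=1e-12)

    def test_fast_path_matches_dense_sum(
        self, posterior_mean_params, constants, prior, synthetic_161
    ):
        fast = log_likelihood(posterior_mean_params, synthetic_161, constants, prior)
        dense = log_likelihood_dense(
            posterior_mean_params, synthetic_161, constants, prior
        )
        assert fast == pytest.approx(dense, rel=1e-10)


class TestPropose:
    def test_zero_scales_return_params_unchanged(self, posterior_mean_params):
        rng = np.random.default_rng(0)
        out = propose(posterior_mean_params, np.zeros(4), rng)
        np.testing.assert_array_equal(out.as_array(), posterior_mean_params.as_array())

    def test_empirical_sd_matches_scale(self, posterior_mean_params):
        rng = np.random.default_rng(1)
        scales = 0.05 * np.abs(posterior_mean_params.as_array())
        draws = np.array(
            [propose(posterior_mean_params, scales, rng).b for _ in range(100_000)]
        )
        assert draws.std() == pytest.approx(scales[1], rel=0.02)

    def test_symmetry(self, posterior_mean_params):
        rng = np.random.default_rng(2)
        scales = 0.05 * np.abs(posterior_mean_params.as_array())
        diffs = np.array(
            [
                propose(posterior_mean_params, scales, rng).as_array()
                - posterior_mean_params.as_array()
                for _ in range(50_000)
            ]
        )
        np.testing.assert_allclose(
            diffs.mean(axis=0) / scales, np.zeros(4), atol=0.02
        )


class TestMetropolisHastings:
    def test_same_seed_identical_chains(self, synthetic_161, constants, prior):
        init = moment_match_init(synthetic_161, constants, prior)
        cfg = MCMCConfig(iterations=2_000, burn_in=100, seed=5)
        c1 = metropolis_hastings(synthetic_161, init, cfg, constants, prior)
        c2 = metropolis_hastings(synthetic_161, init, cfg, constants, prior)
        np.testing.assert_array_equal(c1.draws, c2.draws)
        np.testing.assert_array_equal(c1.accepted, c2.accepted)

    def test_infinite_init_raises_with_guidance(self, synthetic_161, constants, prior):
        bad = ScalingParams(a=1e-14, b=constants.beta, c_bar=1.0, d=1.0)
        with pytest.raises(ValueError, match="moment_match_init"):
            metropolis_hastings(
                synthetic_161, bad, MCMCConfig(iterations=100, burn_in=10), constants, prior
            )

    def test_single_parameter_grid_posterior_oracle(
        self, posterior_mean_params, constants, prior, synthetic_161
    ):
        """Fixing b, c_bar, d and inferring only the prefactor a, the MH
        posterior mean must agree with a dense-grid quadrature of the same
        posterior to better than 1%."""
        truth = posterior_mean_params

        def loglik_a(a_arr):
            p = ScalingParams(float(a_arr[0]), truth.b, truth.c_bar, truth.d)
            return log_likelihood(p, synthetic_161, constants, prior)

        # dense grid posterior (flat prior on a > 0)
        grid = np.linspace(truth.a / 4, truth.a * 4, 2000)
        logpost = np.array([loglik_a([a]) for a in grid])
        w = np.exp(logpost - logpost.max())
        grid_mean = float(np.trapezoid(w * grid, grid) / np.trapezoid(w, grid))

        def logpost_vec(theta):
            if theta[0] <= 0:
                return -math.inf
            return loglik_a(theta)

        rng = np.random.default_rng(9)
        draws, _, _, _ = metropolis_hastings_core(
            logpost_vec, np.array([truth.a]), np.array([0.05 * truth.a]), 60_000, rng
        )
        mh_mean = float(draws[10_000:, 0].mean())
        assert mh_mean == pytest.approx(grid_mean, rel=0.01)

    def test_detailed_balance_two_basin_frequencies(self):
        """Stationary occupancy of a sharp two-component mixture matches the
        mixture weights (a discrete two-point approximation of balance)."""
        w1, w2 = 0.3, 0.7

        def logpost(theta):
            x = theta[0]
            return math.log(
                w1 * math.exp(-0.5 * (x / 0.5) ** 2)
                + w2 * math.exp(-0.5 * ((x - 5.0) / 0.5) ** 2)
            )

        rng = np.random.default_rng(17)
        draws, _, _, _ = metropolis_hastings_core(
            logpost, np.array([0.0]), np.array([2.5]), 200_000, rng
        )
        frac_upper = float(np.mean(draws[20_000:, 0] > 2.5))
        assert frac_upper == pytest.approx(w2, abs=0.03)

    def test_recovery_within_three_posterior_sds(
        self, posterior_mean_params, constants, prior
    ):
        from allokin import SyntheticConfig, generate_dataset

        rs = generate_dataset(SyntheticConfig(n=200, seed=42))
        init = moment_match_init(rs, constants, prior)
        cfg = MCMCConfig(iterations=100_000, burn_in=20_000, seed=43)
        chain = metropolis_hastings(rs, init, cfg, constants, prior)
        summ = summarize_posterior(chain)
        truth = posterior_mean_params.as_array()
        for j, name in enumerate(ScalingParams.names):
            pull = abs(summ.mean[name] - truth[j]) / summ.sd[name]
            assert pull < 3.0, f"{name}: posterior pull {pull:.2f}"
        # posterior sd of b is the right order for n~161-200 data
        assert 0.02 < summ.sd["b"] < 0.5


class TestSummarizePosterior:
    def _chain(self, draws, burn_in=10):
        from allokin.mcmc import MarkovChain

        n = draws.shape[0]
        return MarkovChain(
            draws=draws,
            log_likelihoods=np.zeros(n),
            accepted=np.ones(n, dtype=bool),
            acceptance_rate=np.full(4, 0.3),
            seed=0,
            config=MCMCConfig(iterations=n, burn_in=burn_in),
        )

    def test_constant_chain_flagged_degenerate(self):
        chain = self._chain(np.ones((500, 4)), burn_in=10)
        summ = summarize_posterior(chain)
        assert summ.sd["b"] == 0.0
        assert math.isnan(summ.ess["b"])
        assert any("degenerate" in w for w in summ.warnings)

    def test_iid_pseudo_chain_matches_sample_moments(self):
        rng = np.random.default_rng(4)
        draws = rng.normal([1.0, 2.0, 3.0, 4.0], [0.1, 0.2, 0.3, 0.4], size=(5000, 4))
        chain = self._chain(draws, burn_in=1000)
        summ = summarize_posterior(chain)
        post = draws[1000:]
        np.testing.assert_allclose(summ.mean.to_numpy(), post.mean(axis=0), rtol=1e-12)
        np.testing.assert_allclose(
            summ.sd.to_numpy(), post.std(axis=0, ddof=1), rtol=1e-12
        )
        assert (summ.quantiles["2.5%"] < summ.quantiles["50%"]).all()
        assert (summ.quantiles["50%"] < summ.quantiles["97.5%"]).all()

    def test_burn_in_exceeding_length_is_an_error(self):
        chain = self._chain(np.ones((100, 4)))
        with pytest.raises(ValueError):
            summarize_posterior(chain, burn_in=100)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCConfig(proposal_fraction=0.0)
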