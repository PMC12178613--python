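"""Lognormal change-of-variables machinery and moment-matched initialisation."""

import math

import numpy as np
import pytest
from scipy import integrate, stats as sps

from allokin import (
    CellSizePrior,
    DegenerateMapError,
    KineticRecord,
    LogNormalSpec,
    RecordSet,
    ScalingParams,
    km_distribution,
    km_from_volume,
    lognormal_logpdf,
    moment_match_init,
    vmaxdw_distribution,
    vmaxdw_from_volume,
)


class TestInducedSpecs:
    def test_unit_propagation(self, constants):
        p = ScalingParams(a=constants.alpha, b=constants.beta + 1, c_bar=1.0, d=1.0)
        prior = CellSizePrior(spec=LogNormalSpec(0.0, 1.0))
        spec = vmaxdw_distribution(p, constants, prior)
        assert spec.meanlog == pytest.approx(0.0)
        assert spec.sdlog == pytest.approx(1.0)

    def test_posterior_mean_sdlog(self, posterior_mean_params, constants, prior):
        spec = vmaxdw_distribution(posterior_mean_params, constants, prior)
        assert spec.sdlog == pytest.approx(abs(2.70 - 0.920) * 1.49)
        assert spec.sdlog == pytest.approx(2.6522, abs=1e-4)

    def test_km_sdlog_scales_by_d(self, posterior_mean_params, constants, prior):
        sv = vmaxdw_distribution(posterior_mean_params, constants, prior)
        sk = km_distribution(posterior_mean_params, constants, prior)
        assert sk.sdlog / sv.sdlog == pytest.approx(posterior_mean_params.d)
        assert sk.sdlog == pytest.approx(1.254 * (2.70 - 0.920) * 1.49, rel=1e-12)

    def test_km_spec_matches_vmaxdw_when_d_unity(self, constants, prior):
        p = ScalingParams(a=2e-15, b=2.2, c_bar=1.0, d=1.0)
        assert km_distribution(p, constants, prior) == vmaxdw_distribution(
            p, constants, prior
        )

    def test_degenerate_cases_raise(self, constants, prior):
        with pytest.raises(DegenerateMapError):
            vmaxdw_distribution(
                ScalingParams(a=1e-14, b=constants.beta, c_bar=1.0, d=1.0),
                constants,
                prior,
            )
        with pytest.raises(DegenerateMapError):
            km_distribution(
                ScalingParams(a=1e-14, b=2.0, c_bar=1.0, d=0.0), constants, prior
            )

    def test_pushforward_matches_analytic_specs(
        self, posterior_mean_params, constants, prior
    ):
        """Change-of-variables oracle: samples pushed through the forward maps
        are indistinguishable (two-sample KS < 0.01 at n=1e5) from direct
        draws from the analytic lognormal specs."""
        n = 100_000
        rng = np.random.default_rng(7)
        vcell = prior.spec.rvs(n, rng)
        pushed_v = vmaxdw_from_volume(vcell, posterior_mean_params, constants)
        pushed_k = km_from_volume(vcell, posterior_mean_params, constants)
        spec_v = vmaxdw_distribution(posterior_mean_params, constants, prior)
        spec_k = km_distribution(posterior_mean_params, constants, prior)
        direct_v = spec_v.rvs(n, rng)
        direct_k = spec_k.rvs(n, rng)
        ks_v = sps.ks_2samp(pushed_v, direct_v).statistic
        ks_k = sps.ks_2samp(pushed_k, direct_k).statistic
        assert ks_v < 0.01
        assert ks_k < 0.01


class TestLogPdf:
    def test_standard_closed_form(self):
        assert lognormal_logpdf(1.0, LogNormalSpec(0.0, 1.0)) == pytest.approx(
            -math.log(math.sqrt(2 * math.pi))
        )

    def test_matches_scipy(self):
        spec = LogNormalSpec(-1.3, 0.7)
        x = np.logspace(-3, 2, 50)
        np.testing.assert_allclose(
            lognormal_logpdf(x, spec), spec.frozen().logpdf(x), rtol=1e-10
        )

    def test_mode_matches_numerical_argmax(self):
        spec = LogNormalSpec(0.4, 0.9)
        grid = np.linspace(1e-4, 5.0, 200_001)
        numerical = grid[np.argmax(lognormal_logpdf(grid, spec))]
        assert numerical == pytest.approx(spec.mode, rel=1e-3)
        assert spec.mode == pytest.approx(math.exp(0.4 - 0.81))

    def test_density_integrates_to_one(self):
        spec = LogNormalSpec(-0.5, 1.2)
        total, _ = integrate.quad(lambda x: math.exp(lognormal_logpdf(x, spec)), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_returns_minus_inf_not_exception(self):
        spec = LogNormalSpec(0.0, 1.0)
        assert lognormal_logpdf(0.0, spec) == -np.inf
        assert lognormal_logpdf(-3.0, spec) == -np.inf


def _recordset_from_arrays(v, k):
    recs = [KineticRecord(f"v{i}", "g", vmax_dw=float(x)) for i, x in enumerate(v)]
    recs += [KineticRecord(f"k{i}", "g", km=float(x)) for i, x in enumerate(k)]
    return RecordSet(recs)


class TestMomentMatchInit:
    def test_recovers_truth_from_large_simulation(
        self, posterior_mean_params, constants, prior
    ):
        spec_v = vmaxdw_distribution(posterior_mean_params, constants, prior)
        spec_k = km_distribution(posterior_mean_params, constants, prior)
        rng = np.random.default_rng(11)
        n = 100_000
        rs = _recordset_from_arrays(spec_v.rvs(n, rng), spec_k.rvs(n, rng))
        est = moment_match_init(rs, constants, prior)
        truth = posterior_mean_params
        assert est.b == pytest.approx(truth.b, rel=0.02)
        assert est.d == pytest.approx(truth.d, rel=0.02)
        assert math.log(est.a) == pytest.approx(math.log(truth.a), rel=0.02)
        assert math.log(est.c_bar) == pytest.approx(math.log(truth.c_bar), rel=0.05)

    def test_exact_inverse_of_analytic_moments(self, constants, prior):
        """moment matching composed with the analytic moments is the identity
        (positive-root branch b > beta)."""
        truth = ScalingParams(a=3.1e-15, b=2.4, c_bar=0.05, d=0.8)
        spec_v = vmaxdw_distribution(truth, constants, prior)
        spec_k = km_distribution(truth, constants, prior)

        # two-point samples engineered to hit the distributions' log moments
        def two_point(spec):
            return np.exp([spec.meanlog - spec.sdlog / math.sqrt(2),
                           spec.meanlog + spec.sdlog / math.sqrt(2)])

        rs = _recordset_from_arrays(two_point(spec_v), two_point(spec_k))
        est = moment_match_init(rs, constants, prior)
        assert est.a == pytest.approx(truth.a, rel=1e-10)
        assert est.b == pytest.approx(truth.b, rel=1e-10)
        assert est.c_bar == pytest.approx(truth.c_bar, rel=1e-10)
        assert est.d == pytest.approx(truth.d, rel=1e-10)

    def test_moment_equations_satisfied(self, constants, prior, synthetic_161):
        est = moment_match_init(synthetic_161, constants, prior)
        spec_v = vmaxdw_distribution(est, constants, prior)
        spec_k = km_distribution(est, constants, prior)
        lv = np.log(synthetic_161.vmax_dw_values())
        lk = np.log(synthetic_161.km_values())
        assert spec_v.meanlog == pytest.approx(lv.mean(), abs=1e-10)
        assert spec_v.sdlog == pytest.approx(lv.std(ddof=1), abs=1e-10)
        assert spec_k.meanlog == pytest.approx(lk.mean(), abs=1e-10)
        assert spec_k.sdlog == pytest.approx(lk.std(ddof=1), abs=1e-10)
        assert est.b > constants.beta  # positive-root branch

    def test_single_record_is_an_error(self, constants, prior):
        rs = _recordset_from_arrays([1e-3], [1e-5])
        with pytest.raises(ValueError):
            moment_match_init(rs, constants, prior)

    def test_zero_spread_is_an_error(self, constants, prior):
        rs = _recordset_from_arrays([1e-3, 1e-3], [1e-5, 2e-5])
        with pytest.raises(ValueError, match="spread"):
            moment_match_init(rs, constants, prior)


class TestCellSizePrior:
    def test_quartile_mass_closed_form(self, prior):
        z1 = (math.log(0.218) + 0.74) / 1.49
        z3 = (math.log(1.048) + 0.74) / 1.49
        expected = sps.norm.cdf(z3) - sps.norm.cdf(z1)
        assert prior.quartile_mass() == pytest.approx(expected, rel=1e-12)

    def test_prior_quartile_ordering_enforced(self):
        with pytest.raises(ValueError):
            CellSizePrior(q1=2.0, q3=1.0)
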