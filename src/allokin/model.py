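"""Model/results interface for the uptake-kinetics scaling analysis.

:class:`UptakeScalingModel` holds the kinetic observations together with the
cell-size prior and weight-volume constants; :meth:`~UptakeScalingModel.fit`
runs the Metropolis-Hastings sampler and returns an
:class:`UptakeScalingResults` carrying posterior means, standard deviations,
credible intervals, mixing diagnostics, prediction and back-prediction
helpers, and a text ``summary()``.

Example
-------
>>> from allokin import SyntheticConfig, generate_dataset, UptakeScalingModel
>>> rs = generate_dataset(SyntheticConfig(seed=1))
>>> model = UptakeScalingModel.from_records(rs)
>>> res = model.fit(iterations=20000, burn_in=5000, seed=1)
>>> res.params["b"]  # doctest: +SKIP
2.68...
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .allometry import (
    AllometryConstants,
    ScalingParams,
    km_from_volume,
    vmaxdw_from_volume,
)
from .distributions import (
    CellSizePrior,
    DEFAULT_CELL_SIZE_PRIOR,
    km_distribution,
    moment_match_init,
    vmaxdw_distribution,
)
from .mcmc import (
    MarkovChain,
    MCMCConfig,
    PosteriorSummary,
    log_likelihood,
    metropolis_hastings,
    summarize_posterior,
)
from .records import RecordSet
from .stats import CoverageResult, vcell_coverage

__all__ = ["UptakeScalingModel", "UptakeScalingResults"]


class UptakeScalingModel:
    """Lognormal scaling model for V_maxDW and K_m observations.

    Parameters
    ----------
    vmax_dw, km : array-like or None
        Observations in canonical units (mol S g^-1 DW h^-1; mol S L^-1).
        Either may be empty; together they must contain data.
    constants : AllometryConstants
        Dry weight-volume conversion constants.
    prior : CellSizePrior
        Lognormal cell-volume prior inducing the trait distributions.
    """

    def __init__(
        self,
        vmax_dw=None,
        km=None,
        constants: AllometryConstants = AllometryConstants(),
        prior: CellSizePrior = DEFAULT_CELL_SIZE_PRIOR,
        records: Optional[RecordSet] = None,
    ):
        if records is not None:
            self.data = records
        else:
            from .records import KineticRecord

            recs = []
            for v in np.atleast_1d(vmax_dw if vmax_dw is not None else []):
                recs.append(
                    KineticRecord("obs", "unlabelled", vmax_dw=float(v))
                )
            for k in np.atleast_1d(km if km is not None else []):
                recs.append(KineticRecord("obs", "unlabelled", km=float(k)))
            self.data = RecordSet(recs, provenance="arrays")
        if len(self.data) == 0:
            raise ValueError("model needs at least one observation")
        self.constants = constants
        self.prior = prior

    @classmethod
    def from_records(
        cls,
        records: RecordSet,
        constants: AllometryConstants = AllometryConstants(),
        prior: CellSizePrior = DEFAULT_CELL_SIZE_PRIOR,
    ) -> "UptakeScalingModel":
        return cls(records=records, constants=constants, prior=prior)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        constants: AllometryConstants = AllometryConstants(),
        prior: CellSizePrior = DEFAULT_CELL_SIZE_PRIOR,
    ) -> "UptakeScalingModel":
        """Build from a dataframe with ``vmax_dw``/``km`` columns (canonical units)."""
        return cls(
            records=RecordSet.from_dataframe(df), constants=constants, prior=prior
        )

    def loglike(self, params: ScalingParams) -> float:
        """Log-likelihood of `params` for this model's data."""
        return log_likelihood(params, self.data, self.constants, self.prior)

    def start_params(self) -> ScalingParams:
        """Moment-matched initial values for the sampler."""
        return moment_match_init(self.data, self.constants, self.prior)

    def fit(
        self,
        iterations: int = 100_000,
        burn_in: int = 20_000,
        proposal_fraction: float = 0.05,
        seed: int = 0,
        start: Optional[ScalingParams] = None,
        update: str = "joint",
        prior_kind: str = "log_flat",
        exclude_partial: bool = False,
    ) -> "UptakeScalingResults":
        """Run Metropolis-Hastings and summarise the posterior."""
        cfg = MCMCConfig(
            iterations=iterations,
            burn_in=burn_in,
            proposal_fraction=proposal_fraction,
            seed=seed,
            update=update,
            prior_kind=prior_kind,
            exclude_partial=exclude_partial,
        )
        if start is None:
            start = self.start_params()
        chain = metropolis_hastings(
            self.data, start, cfg, self.constants, self.prior
        )
        summary = summarize_posterior(chain)
        return UptakeScalingResults(self, chain, summary, start)


class UptakeScalingResults:
    """Posterior estimates of (a, b, c_bar, d) with diagnostics and predictors."""

    def __init__(
        self,
        model: UptakeScalingModel,
        chain: MarkovChain,
        summary: PosteriorSummary,
        start: ScalingParams,
    ):
        self.model = model
        self.chain = chain
        self.posterior = summary
        self.start = start

    # -- statsmodels-flavoured accessors ------------------------------------
    @property
    def params(self) -> pd.Series:
        """Posterior means (the point estimates)."""
        return self.posterior.mean

    @property
    def bse(self) -> pd.Series:
        """Posterior standard deviations."""
        return self.posterior.sd

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Central posterior credible interval per parameter."""
        post = self.chain.draws[self.posterior.burn_in:]
        qs = np.percentile(post, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
        return pd.DataFrame(
            qs.T, index=list(ScalingParams.names), columns=["lower", "upper"]
        )

    @property
    def scaling_params(self) -> ScalingParams:
        return self.posterior.to_params()

    @property
    def llf(self) -> float:
        """Log-likelihood at the posterior-mean parameters."""
        return self.model.loglike(self.scaling_params)

    # -- predictions ---------------------------------------------------------
    def predict_vmaxdw(self, vcell):
        return vmaxdw_from_volume(vcell, self.scaling_params, self.model.constants)

    def predict_km(self, vcell):
        return km_from_volume(vcell, self.scaling_params, self.model.constants)

    def induced_distributions(self):
        """The fitted lognormal specs of V_maxDW and K_m."""
        p = self.scaling_params
        return (
            vmaxdw_distribution(p, self.model.constants, self.model.prior),
            km_distribution(p, self.model.constants, self.model.prior),
        )

    def vcell_coverage(self) -> CoverageResult:
        """Back-predicted cell volumes vs the prior's quartile interval."""
        return vcell_coverage(
            self.model.data, self.scaling_params, self.model.prior, self.model.constants
        )

    def sample_posterior_predictive(
        self, n: int, rng: Optional[np.random.Generator] = None, seed: Optional[int] = None
    ) -> pd.DataFrame:
        """Generate (vcell, vmax_dw, km) triples from the fitted model.

        Parameters are drawn from independent normal approximations of the
        posterior marginals, cell volumes from the size prior; each triple
        uses one shared volume draw (the coupled forward model).
        """
        if rng is None:
            rng = np.random.default_rng(seed)
        mean = self.posterior.mean.to_numpy()
        sd = self.posterior.sd.to_numpy()
        vcell = self.model.prior.spec.rvs(n, rng)
        rows = []
        for i in range(n):
            theta = rng.normal(mean, sd)
            if theta[0] <= 0 or theta[2] <= 0:  # stay on the support
                theta = mean
            p = ScalingParams.from_array(theta)
            rows.append(
                (
                    vcell[i],
                    vmaxdw_from_volume(vcell[i], p, self.model.constants),
                    km_from_volume(vcell[i], p, self.model.constants),
                )
            )
        return pd.DataFrame(rows, columns=["vcell", "vmax_dw", "km"])

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        """Plain-text posterior summary table."""
        s = self.posterior
        ci = self.conf_int()
        lines = [
            "Uptake-kinetics scaling model: Metropolis-Hastings posterior",
            "=" * 64,
            f"records: {len(self.model.data)}   "
            f"vmax_dw: {self.model.data.vmax_dw_values().size}   "
            f"km: {self.model.data.km_values().size}",
            f"draws: {s.n_draws} (after burn-in {s.burn_in})   "
            f"acceptance: {np.mean(np.atleast_1d(s.acceptance_rate)):.3f}",
            "-" * 64,
            f"{'param':>6} {'mean':>12} {'sd':>11} {'2.5%':>11} {'97.5%':>11} "
            f"{'ESS':>7} {'R^':>6}",
        ]
        for name in ScalingParams.names:
            lines.append(
                f"{name:>6} {s.mean[name]:>12.4g} {s.sd[name]:>11.3g} "
                f"{ci.loc[name, 'lower']:>11.4g} {ci.loc[name, 'upper']:>11.4g} "
                f"{s.ess[name]:>7.0f} {s.split_rhat[name]:>6.3f}"
            )
        if s.warnings:
            lines.append("-" * 64)
            lines.extend(f"warning: {w}" for w in s.warnings)
        return "\n".join(lines)

    def __repr__(self) -> str:
        p = self.params
        return (
            f"<UptakeScalingResults b={p['b']:.3f} d={p['d']:.3f} "
            f"n={len(self.model.data)}>"
        )
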