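"""End-to-end orchestration: read -> filter -> fit -> stats -> report.

Outputs are plain CSV/JSON so figures can be re-rendered without re-fitting;
every artefact is stamped with the seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .allometry import AllometryConstants, ScalingParams
from .distributions import CellSizePrior, LogNormalSpec
from .mcmc import MCMCConfig
from .model import UptakeScalingModel
from .records import AnomalyFilterConfig, RecordSet, filter_anomalies, read_records
from .simulate import SyntheticConfig
from .stats import (
    bivariate_fit,
    dip_test,
    ellipse_points,
    group_summaries,
    loglog_regression,
    loglog_regressions_by_group,
    normality_suite,
)

logger = logging.getLogger("allokin")

__all__ = ["RunConfig", "run_full_analysis", "run_stats", "config_hash"]


@dataclass
class RunConfig:
    input_path: Optional[str] = None
    results_dir: str = "results"
    anomaly_filter: AnomalyFilterConfig = field(default_factory=AnomalyFilterConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    constants: AllometryConstants = field(default_factory=AllometryConstants)
    prior: CellSizePrior = field(default_factory=CellSizePrior)
    ellipse_quantile: float = 0.95
    dip_n_boot: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw: dict = {}
        for key in ("input_path", "results_dir", "ellipse_quantile", "dip_n_boot", "seed"):
            if key in raw:
                kw[key] = raw[key]
        if "anomaly_filter" in raw:
            kw["anomaly_filter"] = AnomalyFilterConfig(**raw["anomaly_filter"])
        if "mcmc" in raw:
            kw["mcmc"] = MCMCConfig(**raw["mcmc"])
        if "constants" in raw:
            c = dict(raw["constants"])
            if "alpha_log10" in c:
                c["alpha"] = 10.0 ** c.pop("alpha_log10")
            kw["constants"] = AllometryConstants(**c)
        if "prior" in raw:
            p = dict(raw["prior"])
            spec = LogNormalSpec(
                meanlog=p.pop("meanlog", -0.74), sdlog=p.pop("sdlog", 1.49)
            )
            kw["prior"] = CellSizePrior(spec=spec, **p)
        if "synthetic" in raw:
            s = dict(raw["synthetic"])
            if "params" in s:
                s["params"] = ScalingParams(**s["params"])
            kw["synthetic"] = SyntheticConfig(**s)
        return cls(**kw)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {
            "input_path": self.input_path,
            "results_dir": self.results_dir,
            "anomaly_filter": enc(self.anomaly_filter),
            "mcmc": enc(self.mcmc),
            "synthetic": enc(self.synthetic),
            "constants": enc(self.constants),
            "prior": enc(self.prior),
            "ellipse_quantile": self.ellipse_quantile,
            "dip_n_boot": self.dip_n_boot,
            "seed": self.seed,
        }


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(cfg: RunConfig) -> dict:
    return {"config_hash": config_hash(cfg), "seed": cfg.seed}


def _log_stage(stage: str, t0: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s elapsed=%.2fs %s", stage, time.perf_counter() - t0, extras)


def run_stats(rs: RecordSet, cfg: RunConfig) -> dict:
    """The descriptive-statistics report for one record set."""
    report: dict = {"counts_by_group": rs.counts_by_group(), "n_records": len(rs)}
    report["group_summaries"] = (
        group_summaries(rs).reset_index().to_dict(orient="records")
    )
    lv = np.log(rs.vmax_dw_values())
    lk = np.log(rs.km_values())
    rng = np.random.default_rng(cfg.seed)
    for name, lx in [("vmax_dw", lv), ("km", lk)]:
        entry: dict = {"n": int(lx.size)}
        if lx.size >= 8 and np.ptp(lx) > 0:
            entry["normality"] = normality_suite(lx)
        if lx.size >= 10:
            dip, p = dip_test(np.exp(lx), n_boot=cfg.dip_n_boot, rng=rng)
            entry["dip"] = {"statistic": dip, "p_value": p}
        report[f"log_{name}"] = entry
    v, k = rs.paired_values()
    if v.size >= 3:
        overall = loglog_regression(rs)
        report["regression_all"] = dataclasses.asdict(overall)
        fits, skipped = loglog_regressions_by_group(rs)
        report["regressions_by_group"] = [dataclasses.asdict(f) for f in fits]
        report["regressions_skipped"] = skipped
        fit = bivariate_fit(rs)
        report["bivariate_fit"] = dataclasses.asdict(fit)
    return report


def run_full_analysis(cfg: RunConfig, rs: Optional[RecordSet] = None) -> dict:
    """Execute the whole pipeline and write all artefacts under results_dir.

    `rs` may be passed directly (e.g. a synthetic set); otherwise
    ``cfg.input_path`` is read.  Returns a manifest of written paths plus
    the posterior and stats dictionaries.
    """
    out = Path(cfg.results_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(cfg)
    t0 = time.perf_counter()

    if rs is None:
        if cfg.input_path is None:
            raise ValueError("run_full_analysis needs input_path or an explicit RecordSet")
        rs = read_records(cfg.input_path)
    _log_stage("read", t0, n=len(rs))

    t = time.perf_counter()
    kept, removed = filter_anomalies(rs, cfg.anomaly_filter)
    kept.to_csv(out / "records_clean.csv")
    removed.to_csv(out / "records_removed.csv")
    _log_stage("filter", t, kept=len(kept), removed=len(removed))

    t = time.perf_counter()
    model = UptakeScalingModel.from_records(kept, cfg.constants, cfg.prior)
    res = model.fit(
        iterations=cfg.mcmc.iterations,
        burn_in=cfg.mcmc.burn_in,
        proposal_fraction=cfg.mcmc.proposal_fraction,
        seed=cfg.seed,
        update=cfg.mcmc.update,
    )
    res.chain.to_csv(out / "chain.csv")
    posterior = res.posterior.to_dict() | stamp
    (out / "posterior.json").write_text(json.dumps(posterior, indent=2))
    _log_stage("fit", t, acceptance=float(np.mean(res.posterior.acceptance_rate)))

    t = time.perf_counter()
    stats_report = run_stats(kept, cfg) | stamp
    (out / "stats.json").write_text(json.dumps(stats_report, indent=2, default=float))
    _log_stage("stats", t)

    t = time.perf_counter()
    _write_figure_data(out, kept, res, cfg)
    manifest = {
        "results_dir": str(out),
        "posterior": posterior,
        "stats": stats_report,
        "files": sorted({p.name for p in out.iterdir()} | {"manifest.json"}),
    } | stamp
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    _log_stage("report", t)
    return manifest


def _write_figure_data(out: Path, rs: RecordSet, res, cfg: RunConfig) -> None:
    """Figure-ready CSVs: marginal densities, scaling curves, ellipse, points."""
    spec_v, spec_k = res.induced_distributions()
    for name, spec, values in [
        ("vmax_dw", spec_v, rs.vmax_dw_values()),
        ("km", spec_k, rs.km_values()),
    ]:
        lo = min(spec.meanlog - 4 * spec.sdlog, float(np.log(values).min()))
        hi = max(spec.meanlog + 4 * spec.sdlog, float(np.log(values).max()))
        grid = np.exp(np.linspace(lo, hi, 400))
        dens = spec.frozen().pdf(grid)
        pd.DataFrame({name: grid, "density": dens}).to_csv(
            out / f"density_{name}.csv", index=False
        )

    vgrid = np.logspace(-3, 4, 300)
    pd.DataFrame(
        {
            "vcell": vgrid,
            "vmax_dw": res.predict_vmaxdw(vgrid),
            "km": res.predict_km(vgrid),
        }
    ).to_csv(out / "scaling_curves.csv", index=False)

    cov = res.vcell_coverage()
    cov.estimates.to_csv(out / "vcell_estimates.csv", index=False)

    v, k = rs.paired_values()
    if v.size >= 3:
        fit = bivariate_fit(rs)
        pts = ellipse_points(fit, quantile=cfg.ellipse_quantile)
        pd.DataFrame(pts, columns=["log10_vmax_dw", "log10_km"]).to_csv(
            out / "ellipse_observed.csv", index=False
        )
    gen = res.sample_posterior_predictive(500, seed=cfg.seed)
    gen.to_csv(out / "posterior_predictive.csv", index=False)
    logpairs = np.column_stack([np.log10(gen["vmax_dw"]), np.log10(gen["km"])])
    fit_gen = bivariate_fit(logpairs)
    pts = ellipse_points(fit_gen, quantile=cfg.ellipse_quantile)
    pd.DataFrame(pts, columns=["log10_vmax_dw", "log10_km"]).to_csv(
        out / "ellipse_generated.csv", index=False
    )
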