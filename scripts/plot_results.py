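#!/usr/bin/env python
"""Render the figure-data CSVs written by `allokin run`.

Usage: python scripts/plot_results.py <results-dir> [--out figures.png]

Purely cosmetic: every number plotted here comes from the serialized
pipeline outputs, so figures can be re-rendered without re-fitting.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("results_dir", type=Path)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = args.results_dir
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))

    for ax, name, label in [
        (axes[0, 0], "vmax_dw", "V_maxDW (mol S g$^{-1}$ DW h$^{-1}$)"),
        (axes[0, 1], "km", "K_m (mol S L$^{-1}$)"),
    ]:
        dens = pd.read_csv(d / f"density_{name}.csv")
        clean = pd.read_csv(d / "records_clean.csv")[name].dropna()
        ax.hist(np.log10(clean), bins=25, density=True, alpha=0.5, label="records")
        # change of variables to log10 axis: p(log10 x) = ln(10) * x * p(x)
        ax.plot(
            np.log10(dens[name]),
            np.log(10.0) * dens[name] * dens["density"],
            label="fitted lognormal",
        )
        ax.set_xlabel(f"log10 {label}")
        ax.legend()

    curves = pd.read_csv(d / "scaling_curves.csv")
    est = pd.read_csv(d / "vcell_estimates.csv")
    ax = axes[1, 0]
    ax.loglog(curves["vcell"], curves["vmax_dw"], label="fitted V_maxDW")
    ax.loglog(curves["vcell"], curves["km"], label="fitted K_m")
    for var, marker in [("vmax_dw", "."), ("km", "x")]:
        sub = est[est["variable"] == var]
        ax.plot(sub["vcell"], np.ones(len(sub)) * ax.get_ylim()[0] * 2, marker, alpha=0.3)
    ax.set_xlabel("V_cell ($\\mu$m$^3$)")
    ax.legend()

    ax = axes[1, 1]
    obs = pd.read_csv(d / "ellipse_observed.csv")
    gen = pd.read_csv(d / "ellipse_generated.csv")
    pts = pd.read_csv(d / "records_clean.csv").dropna(subset=["vmax_dw", "km"])
    ax.plot(np.log10(pts["vmax_dw"]), np.log10(pts["km"]), ".", alpha=0.4)
    ax.plot(obs["log10_vmax_dw"], obs["log10_km"], "--", label="observed 95%")
    ax.plot(gen["log10_vmax_dw"], gen["log10_km"], ":", label="posterior predictive 95%")
    ax.set_xlabel("log10 V_maxDW")
    ax.set_ylabel("log10 K_m")
    ax.legend()

    fig.tight_layout()
    out = args.out or d / "figures.png"
    fig.savefig(out, dpi=150)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
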