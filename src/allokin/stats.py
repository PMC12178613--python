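"""Descriptive statistics for kinetic-trait compilations.

Group medians and nonparametric comparisons, normality tests on log values,
Hartigan's dip test of unimodality, per-group log-log power-law regressions,
bivariate-normal fits with Mahalanobis confidence ellipses, and cell-volume
back-prediction coverage against the prokaryotic size quartiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .allometry import (
    AllometryConstants,
    ScalingParams,
    volume_from_km,
    volume_from_vmaxdw,
)
from .distributions import CellSizePrior, DEFAULT_CELL_SIZE_PRIOR
from .records import RecordSet

__all__ = [
    "RegressionResult",
    "BivariateFit",
    "CoverageResult",
    "group_summaries",
    "mann_whitney",
    "normality_suite",
    "dip_statistic",
    "dip_test",
    "loglog_regression",
    "loglog_regressions_by_group",
    "bivariate_fit",
    "ellipse_points",
    "vcell_coverage",
]


# --------------------------------------------------------------------------
# Medians and group summaries
# --------------------------------------------------------------------------

def group_summaries(rs: RecordSet) -> pd.DataFrame:
    """Per-group and overall medians/quartiles of both kinetic variables.

    Values are computed on canonical units; the display columns re-express
    the medians in the conventional reporting units (mmol S g^-1 DW h^-1
    for V_maxDW, umol S L^-1 for K_m).
    """
    rows = []
    for label, subset in [("all", rs)] + [(g, rs.subset(group=g)) for g in rs.groups()]:
        v = subset.vmax_dw_values()
        k = subset.km_values()
        rows.append(
            {
                "group": label,
                "n_vmax": v.size,
                "n_km": k.size,
                "vmax_dw_median": np.median(v) if v.size else np.nan,
                "vmax_dw_q1": np.percentile(v, 25) if v.size else np.nan,
                "vmax_dw_q3": np.percentile(v, 75) if v.size else np.nan,
                "km_median": np.median(k) if k.size else np.nan,
                "km_q1": np.percentile(k, 25) if k.size else np.nan,
                "km_q3": np.percentile(k, 75) if k.size else np.nan,
            }
        )
    df = pd.DataFrame(rows).set_index("group")
    df["vmax_dw_median_mmol"] = df["vmax_dw_median"] * 1e3
    df["km_median_umol"] = df["km_median"] * 1e6
    return df


# --------------------------------------------------------------------------
# Mann-Whitney
# --------------------------------------------------------------------------

def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test, normal approximation with tie and
    continuity corrections.

    Returns (U for the first sample, two-sided p).  A fully tied pooled
    sample is degenerate: p = 1 with a warning.  Rank-based, hence invariant
    under any strictly monotone transform applied to the pooled data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all pooled values identical; Mann-Whitney p set to 1")
        return float(x.size * y.size / 2.0), 1.0
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


# --------------------------------------------------------------------------
# Normality suite
# --------------------------------------------------------------------------

def normality_suite(x) -> dict[str, dict[str, float]]:
    """Shapiro-Wilk, Lilliefors-corrected Kolmogorov-Smirnov and
    Anderson-Darling normality tests on (log-transformed) values.

    The KS test uses the estimated-parameter (Lilliefors) null since the
    hypothesised normal's mean and sd come from the sample itself.
    Requires n >= 8; a constant sample has no defined test.
    """
    from statsmodels.stats.diagnostic import lilliefors, normal_ad

    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError(f"normality suite needs n >= 8, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("normality tests are undefined for a constant sample")
    sw_stat, sw_p = sps.shapiro(x)
    ks_stat, ks_p = lilliefors(x, dist="norm")
    ad_stat, ad_p = normal_ad(x)
    return {
        "shapiro_wilk": {"statistic": float(sw_stat), "p_value": float(sw_p)},
        "kolmogorov_smirnov": {"statistic": float(ks_stat), "p_value": float(ks_p)},
        "anderson_darling": {"statistic": float(ad_stat), "p_value": float(ad_p)},
    }


# --------------------------------------------------------------------------
# Hartigan's dip test
# --------------------------------------------------------------------------

def dip_statistic(x) -> float:
    """Hartigan & Hartigan's dip statistic of departure from unimodality.

    Computed by the published iterative greatest-convex-minorant /
    least-concave-majorant construction on the empirical CDF (algorithm
    AS 217): within the current modal interval the closest convex-concave
    pair is found, the largest deviation is recorded, and the interval is
    narrowed until no deviation exceeds the running dip.  The result is
    half the sup-distance to the closest unimodal CDF; it lies in
    [1/(2n), 0.25].
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        return 0.0

    # Hull pointer arrays: mn[j] = previous touch point of the greatest
    # convex minorant ending at j; mj[k] = next touch point of the least
    # concave majorant starting at k.  (0-based indices.)
    mn = np.zeros(n, dtype=np.int64)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (
                j - mnj
            ):
                break
            mn[j] = mnmnj
    mj = np.zeros(n, dtype=np.int64)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (
                k - mjk
            ):
                break
            mj[k] = mjmjk

    low, high = 0, n - 1
    dip = 1.0  # in count units; final statistic is dip / (2n)
    for _ in range(n + 1):  # converges long before; hard guard
        # GCM touch points from high down to low, LCM from low up to high.
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_gcm, l_lcm = len(gcm), len(lcm)
        ix, iv = l_gcm - 2, 1
        ig, ih = l_gcm - 1, l_lcm - 1

        # Largest distance between the two hulls, walking their merged
        # change points from low to high.
        d = 0.0
        if not (l_gcm == 2 and l_lcm == 2):
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig, ih = ix + 1, iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        if d <= dip:
            break

        # Max deviation of the empirical CDF from each hull inside the
        # candidate modal interval.
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            jb, je = gcm[j + 1], gcm[j]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if t > max_t:
                        max_t = t
            if max_t > dip_l:
                dip_l = max_t
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            jb, je = lcm[j], lcm[j + 1]
            max_t = 1.0
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if t > max_t:
                        max_t = t
            if max_t > dip_u:
                dip_u = max_t

        dip = max(dip, dip_l, dip_u)
        low, high = gcm[ig], lcm[ih]
    return dip / (2.0 * n)


def dip_test(
    x,
    n_boot: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Dip statistic with a bootstrap p-value under the uniform null.

    The null distribution of the dip is simulated from `n_boot` uniform
    samples of the same size (the dip is invariant to monotone transforms,
    so any continuous unimodal null gives the same distribution as the
    least-favourable uniform); p is the fraction of null dips >= observed.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError(f"dip test needs n >= 10, got {x.size}")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; bootstrap p will be coarse")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = dip_statistic(x)
    null = np.array([dip_statistic(rng.uniform(size=x.size)) for _ in range(n_boot)])
    p = float(np.mean(null >= observed))
    return observed, p


def dip_pvalues_shared_null(samples: list[np.ndarray], n_boot: int, rng) -> np.ndarray:
    """p-values for same-size samples against one shared bootstrap null table."""
    n = samples[0].size
    null = np.sort([dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)])
    dips = np.array([dip_statistic(s) for s in samples])
    return 1.0 - np.searchsorted(null, dips, side="left") / n_boot


# --------------------------------------------------------------------------
# Log-log regressions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    """OLS of log10(K_m) on log10(V_maxDW); slope is the exponent d."""

    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    n: int
    group: str = "all"

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1:
            raise ValueError(f"r_squared out of [0,1]: {self.r_squared}")
        if self.n < 3:
            raise ValueError(f"regression needs n >= 3, got {self.n}")


def loglog_regression(
    rs: RecordSet, group: Optional[str] = None, method: str = "ols"
) -> RegressionResult:
    """Power-law fit K_m = c * V_maxDW^d on log10 axes for paired records.

    `method` "ols" (default) regresses log10 K_m on log10 V_maxDW; "rma"
    (reduced major axis) is available for trade-off-literature comparisons.
    """
    subset = rs.subset(group=group) if group is not None else rs
    v, k = subset.paired_values()
    if v.size < 3:
        raise ValueError(
            f"group {group or 'all'!r} has {v.size} paired records; need >= 3"
        )
    lx, ly = np.log10(v), np.log10(k)
    n = int(v.size)
    r = float(np.corrcoef(lx, ly)[0, 1])
    r2 = r * r
    if method == "ols":
        slope, intercept = np.polyfit(lx, ly, 1)
    elif method == "rma":
        slope = math.copysign(np.std(ly, ddof=1) / np.std(lx, ddof=1), r)
        intercept = float(np.mean(ly) - slope * np.mean(lx))
    else:
        raise ValueError(f"unknown regression method {method!r}")
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        adjusted_r_squared=float(adj),
        n=n,
        group=group or "all",
    )


def loglog_regressions_by_group(
    rs: RecordSet, min_n: int = 4, method: str = "ols"
) -> tuple[list[RegressionResult], list[dict]]:
    """Per-functional-group regressions for groups with n > 3 pairs.

    Returns (fits, skipped) where each skipped entry records the group and
    its pair count; under-sampled groups are reported, never silently lost.
    """
    fits, skipped = [], []
    for g in rs.groups():
        v, _ = rs.subset(group=g).paired_values()
        if v.size < min_n:
            skipped.append({"group": g, "n_pairs": int(v.size), "reason": f"n < {min_n}"})
            continue
        fits.append(loglog_regression(rs, group=g, method=method))
    return fits, skipped


# --------------------------------------------------------------------------
# Bivariate-normal fit and confidence ellipse
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BivariateFit:
    """Bivariate normal fitted to (log10 V_maxDW, log10 K_m) pairs."""

    mu1: float
    mu2: float
    s11: float
    s12: float
    s22: float
    n: int

    def __post_init__(self) -> None:
        if not (self.s11 > 0 and self.s22 > 0):
            raise ValueError("variances must be positive")
        if not self.s11 * self.s22 - self.s12 ** 2 > 0:
            raise ValueError("covariance matrix is singular or indefinite")

    @property
    def mean(self) -> np.ndarray:
        return np.array([self.mu1, self.mu2])

    @property
    def cov(self) -> np.ndarray:
        return np.array([[self.s11, self.s12], [self.s12, self.s22]])


def bivariate_fit(rs_or_pairs) -> BivariateFit:
    """Sample mean and covariance of the log10 kinetic pairs.

    Accepts a RecordSet (its paired records are used) or a (2, n)/(n, 2)
    array of log10 values.  Raises on a singular covariance.
    """
    if isinstance(rs_or_pairs, RecordSet):
        v, k = rs_or_pairs.paired_values()
        if v.size < 3:
            raise ValueError("bivariate fit needs >= 3 paired records")
        data = np.column_stack([np.log10(v), np.log10(k)])
    else:
        data = np.asarray(rs_or_pairs, dtype=float)
        if data.shape[0] == 2 and data.shape[1] != 2:
            data = data.T
    mu = data.mean(axis=0)
    cov = np.cov(data, rowvar=False, ddof=1)
    return BivariateFit(
        mu1=float(mu[0]),
        mu2=float(mu[1]),
        s11=float(cov[0, 0]),
        s12=float(cov[0, 1]),
        s22=float(cov[1, 1]),
        n=data.shape[0],
    )


def ellipse_points(
    fit: BivariateFit, quantile: float = 0.95, n_points: int = 200
) -> np.ndarray:
    """Mahalanobis confidence ellipse of the fitted bivariate normal.

    The boundary is {x : (x-mu)' Sigma^-1 (x-mu) = chi2_2(quantile)}
    (5.991 at the 0.95 quantile).  Returns an (n_points, 2) closed curve.
    """
    r2 = sps.chi2.ppf(quantile, df=2)
    theta = np.linspace(0.0, 2.0 * math.pi, n_points)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    L = np.linalg.cholesky(fit.cov)
    return fit.mean + math.sqrt(r2) * circle @ L.T


def mahalanobis_sq(points: np.ndarray, fit: BivariateFit) -> np.ndarray:
    """Squared Mahalanobis distance of (n, 2) points from the fitted normal."""
    diff = np.asarray(points, dtype=float) - fit.mean
    solved = np.linalg.solve(fit.cov, diff.T)
    return np.einsum("ij,ji->i", diff, solved)


# --------------------------------------------------------------------------
# Cell-volume back-prediction coverage
# --------------------------------------------------------------------------

@dataclass
class CoverageResult:
    """Back-predicted cell volumes and their coverage of the prior quartiles."""

    estimates: pd.DataFrame  # columns: vcell, variable, inside
    fraction_inside: float
    vmin: float
    vmax: float
    q1: float
    q3: float


def vcell_coverage(
    rs: RecordSet,
    params: ScalingParams,
    prior: CellSizePrior = DEFAULT_CELL_SIZE_PRIOR,
    constants: AllometryConstants = AllometryConstants(),
) -> CoverageResult:
    """Invert the fitted scaling maps record-by-record to cell volumes.

    Each V_maxDW value is pushed through the inverse of its volume power law
    and each K_m value through the composed inverse; the statistic is the
    fraction of all such estimates falling inside the prior's observed
    interquartile interval [q1, q3], plus the overall min-max range.
    """
    rows = []
    for r in rs:
        if r.vmax_dw is not None:
            rows.append(("vmax_dw", volume_from_vmaxdw(r.vmax_dw, params, constants)))
        if r.km is not None:
            rows.append(("km", volume_from_km(r.km, params, constants)))
    if not rows:
        raise ValueError("no records with usable values")
    df = pd.DataFrame(rows, columns=["variable", "vcell"])
    df["inside"] = (df["vcell"] >= prior.q1) & (df["vcell"] <= prior.q3)
    return CoverageResult(
        estimates=df,
        fraction_inside=float(df["inside"].mean()),
        vmin=float(df["vcell"].min()),
        vmax=float(df["vcell"].max()),
        q1=prior.q1,
        q3=prior.q3,
    )
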