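"""Observational statistics on station CO2 measurement tables.

Measurement tables are delimited text with the columns

    site, datetime, co2_ppmv, d13C_permil, d18O_permil, d17O_permil, D17O_permil

(δ values ‰ vs V-SMOW except δ13C vs VPDB; ``D17O_permil`` is the
logarithmic Δ17O at λ = 0.516).  δ17O may be absent when Δ17O is supplied
and vice versa; whichever is missing is filled from the other.

Provides per-site summaries, the unweighted multi-site average, the
geometric-mean (reduced-major-axis) regression in ln(1+δ) space used for
the three-isotope slope, per-record log-ratio statistics, and λ-convention
rescaling of whole datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .constants import LAMBDA_REFERENCE, PERMIL
from .iso_algebra import cap17_log, d17_from_cap_log, rescale_lambda_value

__all__ = [
    "MEASUREMENT_COLUMNS", "read_measurements", "write_measurements",
    "SiteSummary", "RegressionResult", "site_summary", "multi_site_average",
    "gm_regression", "mean_log_ratio", "rescale_dataset",
]

MEASUREMENT_COLUMNS = ["site", "datetime", "co2_ppmv", "d13C_permil",
                       "d18O_permil", "d17O_permil", "D17O_permil"]

#: Tolerance (‰) for consistency between a record's δ17O and its Δ17O.
CAP_CONSISTENCY_TOL = 0.002


def read_measurements(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a measurement table, filling δ17O↔Δ17O from each other."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns
               and c not in ("d17O_permil", "D17O_permil")]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if "d17O_permil" not in df.columns and "D17O_permil" not in df.columns:
        raise ValueError(f"{path}: need at least one of d17O_permil / D17O_permil")
    df["datetime"] = pd.to_datetime(df["datetime"])
    if "D17O_permil" not in df.columns:
        df["D17O_permil"] = cap17_log(df["d17O_permil"].to_numpy(),
                                      df["d18O_permil"].to_numpy())
    elif "d17O_permil" not in df.columns:
        df["d17O_permil"] = d17_from_cap_log(df["D17O_permil"].to_numpy(),
                                             df["d18O_permil"].to_numpy())
    else:
        df["D17O_permil"] = df["D17O_permil"].fillna(
            pd.Series(cap17_log(df["d17O_permil"].to_numpy(),
                                df["d18O_permil"].to_numpy()), index=df.index))
    if validate:
        implied = cap17_log(df["d17O_permil"].to_numpy(), df["d18O_permil"].to_numpy())
        bad = np.abs(implied - df["D17O_permil"].to_numpy()) > CAP_CONSISTENCY_TOL
        if np.any(bad):
            raise ValueError(f"{path}: {int(bad.sum())} records with "
                             f"Delta-17O inconsistent with (d17O, d18O) beyond "
                             f"{CAP_CONSISTENCY_TOL} permil")
        ppm = df["co2_ppmv"].to_numpy()
        if np.any((ppm <= 300) | (ppm >= 600)):
            raise ValueError(f"{path}: CO2 mixing ratios outside the "
                             "(300, 600) ppmv plausibility band")
    return df[MEASUREMENT_COLUMNS]


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float           # permil (intercept in the ln-space fit, x1000)
    r2: float
    slope_se: float
    intercept_se: float
    n: int
    method: str                # "rma" | "ols"


@dataclass(frozen=True)
class SiteSummary:
    site: str
    n: int
    stats: pd.DataFrame         # per variable: mean, sd, se
    regression: RegressionResult
    log_ratio_mean: float       # mean ln(1+d17)/ln(1+d18)
    log_ratio_se: float
    filter_applied: str


def gm_regression(x, y, method: str = "rma") -> RegressionResult:
    """Geometric-mean (reduced-major-axis) or OLS line fit.

    RMA slope = sign(corr)·sd(y)/sd(x): symmetric in x and y, appropriate
    when both variables carry comparable error.  Slope standard error uses
    the standard RMA formula |slope|·sqrt((1 − r²)/n).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0:
        raise ValueError("x has zero variance")
    r = float(np.corrcoef(x, y)[0, 1]) if sy > 0 else 0.0
    if method == "rma":
        slope = (np.sign(r) if r != 0 else 1.0) * sy / sx
    elif method == "ols":
        slope = r * sy / sx if sy > 0 else 0.0
    else:
        raise ValueError(f"method must be 'rma' or 'ols', got {method!r}")
    intercept = float(np.mean(y) - slope * np.mean(x))
    r2 = r ** 2
    slope_se = abs(slope) * np.sqrt(max(1.0 - r2, 0.0) / n)
    intercept_se = slope_se * float(np.sqrt(np.mean(x ** 2)))
    return RegressionResult(slope=float(slope), intercept=intercept, r2=r2,
                            slope_se=float(slope_se), intercept_se=float(intercept_se),
                            n=n, method=method)


def site_summary(df: pd.DataFrame, site: str | None = None,
                 d18_min: float | None = 38.5,
                 regression_method: str = "rma") -> SiteSummary:
    """Summary statistics for one site's measurement table.

    Means/sds/ses are computed over ALL records; the three-isotope slope
    regression excludes records with δ18O below ``d18_min`` (the published
    outlier rule applies only to the fit).  Requires ≥ 2 records.
    """
    if site is not None:
        df = df[df["site"] == site]
    if len(df) < 2:
        raise ValueError("need at least 2 records for a summary (sd undefined)")
    site_name = site if site is not None else str(df["site"].iloc[0])

    variables = ["co2_ppmv", "d13C_permil", "d18O_permil", "d17O_permil", "D17O_permil"]
    table = {}
    n = len(df)
    for var in variables:
        vals = df[var].to_numpy(float)
        sd = float(np.std(vals, ddof=1))
        table[var] = {"mean": float(np.mean(vals)), "sd": sd, "se": sd / np.sqrt(n)}
    stats_df = pd.DataFrame(table).T[["mean", "sd", "se"]]

    if d18_min is not None:
        fit = df[df["d18O_permil"] >= d18_min]
        filter_desc = f"regression excludes d18O < {d18_min} permil ({len(df) - len(fit)} records)"
    else:
        fit = df
        filter_desc = "no filter"
    if len(fit) < 3:
        raise ValueError("fewer than 3 records remain for the slope regression")
    lx = np.log1p(fit["d18O_permil"].to_numpy(float) * PERMIL) / PERMIL
    ly = np.log1p(fit["d17O_permil"].to_numpy(float) * PERMIL) / PERMIL
    reg = gm_regression(lx, ly, method=regression_method)

    ratio_mean, ratio_se = mean_log_ratio(df)
    return SiteSummary(site=site_name, n=n, stats=stats_df, regression=reg,
                       log_ratio_mean=ratio_mean, log_ratio_se=ratio_se,
                       filter_applied=filter_desc)


def multi_site_average(site_means) -> tuple[float, float]:
    """Unweighted mean of site means and its standard error sd/√n.

    Each station counts once regardless of its sample size — the estimator
    behind the multi-site tropospheric Δ17O.  Permutation invariant.
    """
    means = np.asarray(list(site_means), float)
    if means.size < 2:
        raise ValueError("need at least 2 site means")
    return float(np.mean(means)), float(np.std(means, ddof=1) / np.sqrt(means.size))


def mean_log_ratio(df: pd.DataFrame) -> tuple[float, float]:
    """Mean per-record ratio ln(1+δ17O)/ln(1+δ18O), with its standard error."""
    d17 = df["d17O_permil"].to_numpy(float)
    d18 = df["d18O_permil"].to_numpy(float)
    if np.any(d18 == 0):
        raise ValueError("log ratio undefined for records with d18O = 0")
    ratios = np.log1p(d17 * PERMIL) / np.log1p(d18 * PERMIL)
    se = float(np.std(ratios, ddof=1) / np.sqrt(ratios.size)) if ratios.size > 1 else 0.0
    return float(np.mean(ratios)), se


def rescale_dataset(df: pd.DataFrame, lam_from: float,
                    lam_to: float = LAMBDA_REFERENCE) -> pd.DataFrame:
    """Re-express every record's Δ17O under another λ convention.

    Cross-lab consistency operation: datasets reported at a different λ are
    rescaled record-wise using each record's own δ18O.
    """
    if df["d18O_permil"].isna().any():
        raise ValueError("per-record d18O required for lambda rescaling")
    out = df.copy()
    out["D17O_permil"] = rescale_lambda_value(
        df["D17O_permil"].to_numpy(float), lam_from, lam_to,
        df["d18O_permil"].to_numpy(float))
    return out
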