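"""Longitudinal brain-age-gap quantities: BAG rates, age-effect regression
and scan-rescan reproducibility.

The per-participant rate of change in the brain-age gap is

    R_BAG = (delta_t2 - delta_t1) / dT          [years of BAG per year]

with ``dT`` the inter-scan interval and ``AvgAge = (Age_t1 + Age_t2)/2`` the
regressor for longitudinal age effects (a balanced choice that is robust to
interval differences between participants). Display conversions use 12
months/year and 365.25 days/year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "compute_rbag",
    "icc_absolute_agreement",
    "age_effect_regression",
    "reproducibility_stats",
    "AgeEffectResult",
    "ReproducibilityStats",
    "years_to_months",
    "months_to_years",
    "years_to_days",
]

DAYS_PER_YEAR = 365.25
MONTHS_PER_YEAR = 12.0


def years_to_months(v):
    return np.asarray(v, dtype=float) * MONTHS_PER_YEAR


def months_to_years(v):
    return np.asarray(v, dtype=float) / MONTHS_PER_YEAR


def years_to_days(v):
    return np.asarray(v, dtype=float) * DAYS_PER_YEAR


def compute_rbag(
    bag_t1: pd.DataFrame,
    bag_t2: pd.DataFrame,
    cohort: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Merge per-session BAG records into per-participant rate records.

    ``bag_t1``/``bag_t2`` are BagRecord tables (columns participant_id,
    session, Y, Y_B, delta_raw, delta) from :class:`BrainAgeResults.predict`.
    Returns one row per participant with exact arithmetic:
    ``r_bag = (delta_t2 - delta_t1)/dT``, ``avg_age = (Y_t1 + Y_t2)/2`` and
    ``dT = Y_t2 - Y_t1``. Group labels and covariates are joined from
    ``cohort`` when given.
    """
    if set(bag_t1["session"].unique()) & set(bag_t2["session"].unique()):
        raise ValueError("bag_t1 and bag_t2 must come from different sessions")
    m = bag_t1.merge(
        bag_t2, on="participant_id", suffixes=("_t1", "_t2"), validate="one_to_one"
    )
    if m.empty:
        raise ValueError("no participants shared between sessions")
    dt = m["Y_t2"].to_numpy() - m["Y_t1"].to_numpy()
    if (dt <= 0).any():
        raise ValueError("inter-scan interval must be positive for every participant")
    out = pd.DataFrame(
        {
            "participant_id": m["participant_id"],
            "delta_t1": m["delta_t1"],
            "delta_t2": m["delta_t2"],
            "dT": dt,
            "r_bag": (m["delta_t2"].to_numpy() - m["delta_t1"].to_numpy()) / dt,
            "avg_age": (m["Y_t1"].to_numpy() + m["Y_t2"].to_numpy()) / 2.0,
            "yb_t1": m["Y_B_t1"],
            "yb_t2": m["Y_B_t2"],
            "age_t1": m["Y_t1"],
            "age_t2": m["Y_t2"],
        }
    )
    for col in ("sex_t1", "tissue_t1"):
        if col in m:
            out[col.replace("_t1", "")] = m[col]
    if cohort is not None:
        keep = [
            c
            for c in cohort.columns
            if c
            in (
                "participant_id",
                "group",
                "group_main",
                "covid_status",
                "sex",
                "isi",
            )
            or c.startswith("dep_")
        ]
        out = out.merge(
            cohort[keep], on="participant_id", how="left", suffixes=("", "_cohort")
        )
    return out


@dataclass
class AgeEffectResult:
    """OLS of R_BAG on average age within one group."""

    group: str
    slope: float  # years-of-BAG per year, per year of average age
    slope_days: float  # same, expressed in days of BAG per year
    ci: Tuple[float, float]
    p: float
    intercept: float
    n: int

    def summary(self) -> str:
        return (
            f"[{self.group}] R_BAG ~ AvgAge: slope = {self.slope:+.5f} y/y per year "
            f"({self.slope_days:+.1f} days/year), 95% CI "
            f"[{self.ci[0]:+.5f}, {self.ci[1]:+.5f}], p = {self.p:.4g}, n = {self.n}"
        )


def age_effect_regression(
    records: pd.DataFrame,
    group: Optional[str] = None,
    group_col: str = "group_main",
    adjust_sex: bool = False,
) -> AgeEffectResult:
    """Regress the BAG rate on average chronological age (OLS, two-sided p).

    The slope is reported both on the natural scale (years of BAG per year,
    per year of average age) and converted to days/year. Optionally adjusts
    for sex as an additive covariate.
    """
    df = records if group is None else records.loc[records[group_col] == group]
    if len(df) < 10:
        raise ValueError("need at least 10 records for the age-effect regression")
    x = df["avg_age"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("average age is constant; slope undefined")
    exog = pd.DataFrame({"const": 1.0, "avg_age": x})
    if adjust_sex:
        exog["male"] = (df["sex"].to_numpy() == "M").astype(float)
    fit = sm.OLS(df["r_bag"].to_numpy(dtype=float), exog).fit()
    ci = fit.conf_int().loc["avg_age"]
    slope = float(fit.params["avg_age"])
    return AgeEffectResult(
        group=group or "all",
        slope=slope,
        slope_days=float(years_to_days(slope)),
        ci=(float(ci[0]), float(ci[1])),
        p=float(fit.pvalues["avg_age"]),
        intercept=float(fit.params["const"]),
        n=len(df),
    )


@dataclass
class ReproducibilityStats:
    """Scan-rescan agreement of predicted brain ages."""

    pearson_r: float
    pearson_p: float
    icc: float
    icc_ci: Tuple[float, float]
    icc_type: str
    partial_r: float
    partial_p: float
    n: int

    def summary(self) -> str:
        return (
            f"scan-rescan: r = {self.pearson_r:.3f}, {self.icc_type} = "
            f"{self.icc:.3f} (95% CI {self.icc_ci[0]:.3f}-{self.icc_ci[1]:.3f}), "
            f"partial r (age-controlled) = {self.partial_r:.3f}, n = {self.n}"
        )


def _residualise(v: np.ndarray, covar: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), covar])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def icc_absolute_agreement(
    ratings: np.ndarray, conf: float = 0.95, form: str = "ICC2"
) -> Tuple[float, Tuple[float, float]]:
    """ICC from the two-way ANOVA table of an n-subjects x k-raters array.

    ``form='ICC2'``: two-way random effects, absolute agreement, single
    measure — ICC(2,1) = (MSR - MSE) / (MSR + (k-1)MSE + k(MSC - MSE)/n),
    with the McGraw & Wong F-based confidence interval.
    ``form='ICC3'``: two-way mixed, consistency, single measure.
    """
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    alpha = 1.0 - conf
    if form == "ICC3":
        icc = (msr - mse) / (msr + (k - 1) * mse) if (msr + (k - 1) * mse) else np.nan
        f_obs = msr / mse if mse > 0 else np.inf
        f_l = f_obs / sps.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        f_u = f_obs * sps.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        lo = (f_l - 1) / (f_l + k - 1)
        hi = (f_u - 1) / (f_u + k - 1)
        return float(icc), (float(lo), float(hi))
    if form != "ICC2":
        raise ValueError(f"unknown ICC form {form!r}")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else np.nan
    if not np.isfinite(icc) or mse <= np.finfo(float).eps * max(msr, msc, 1.0):
        return float(icc), (float(icc), float(icc))
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return float(icc), (float(lo), float(hi))


def reproducibility_stats(
    yb_t1,
    yb_t2,
    age_t1,
    age_t2,
    icc_form: str = "ICC2",
) -> ReproducibilityStats:
    """Pearson r, intraclass correlation and age-controlled partial r between
    predicted brain ages at the two scans.

    The ICC defaults to ICC(2,1) — two-way random effects, absolute
    agreement, single measure — because the claim under test is stability of
    the same quantity over time; ICC(3,1) (consistency) is available via
    ``icc_form='ICC3'``. The partial correlation residualises each session's
    prediction on its own session's chronological age.
    """
    yb1 = np.asarray(yb_t1, dtype=float)
    yb2 = np.asarray(yb_t2, dtype=float)
    a1 = np.asarray(age_t1, dtype=float)
    a2 = np.asarray(age_t2, dtype=float)
    n = len(yb1)
    if n < 5:
        raise ValueError("need at least 5 paired predictions")
    if yb1.std() == 0 or yb2.std() == 0:
        return ReproducibilityStats(
            np.nan, np.nan, np.nan, (np.nan, np.nan), icc_form, np.nan, np.nan, n
        )
    r, p = sps.pearsonr(yb1, yb2)
    icc, icc_ci = icc_absolute_agreement(
        np.column_stack([yb1, yb2]), form=icc_form
    )

    r1 = _residualise(yb1, a1)
    r2 = _residualise(yb2, a2)
    pr, pp = sps.pearsonr(r1, r2)
    return ReproducibilityStats(
        pearson_r=float(r),
        pearson_p=float(p),
        icc=icc,
        icc_ci=icc_ci,
        icc_type=f"{icc_form}(,1)".replace("ICC2(,1)", "ICC(2,1)").replace(
            "ICC3(,1)", "ICC(3,1)"
        ),
        partial_r=float(pr),
        partial_p=float(pp),
        n=n,
    )
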