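"""Cohort quality control: outlier flagging, interval filtering, group
assignment and covariate-balance diagnostics.

Filter conventions (all configurable):

* IDP outliers: a cell is flagged when it lies more than ``z_threshold``
  (default 5) sample standard deviations from its column mean; zero-variance
  columns flag nothing. A participant-session is excluded when any cell is
  flagged ("any" policy) or when the flagged fraction exceeds a threshold.
* Inter-scan interval (ISI): rows are removed when the ISI falls strictly
  below the cohort's lower percentile (linear-interpolation quantile, ties at
  the threshold retained) or strictly below the absolute minimum in years.
* Groups: Control (G2) when both scans precede the pandemic onset date,
  Pandemic (G1) when exactly one does, split into G3/G4 by COVID status;
  participants with both scans after onset fall outside the design and are
  dropped with a logged reason.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "QCReport",
    "flag_idp_outliers",
    "filter_interscan_interval",
    "assign_groups",
    "balance_table",
    "match_groups",
    "GROUPS",
]

logger = logging.getLogger(__name__)

GROUPS = ("training", "G1", "G2", "G3", "G4")


@dataclass
class QCReport:
    """Row accounting and balance diagnostics for one QC step."""

    step: str
    n_input: int = 0
    n_retained: int = 0
    excluded: Dict[str, int] = field(default_factory=dict)
    details: Optional[pd.DataFrame] = None

    def __post_init__(self):
        pass

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded.values())

    def check_accounting(self) -> None:
        if self.n_input != self.n_retained + self.n_excluded:
            raise AssertionError(
                f"{self.step}: {self.n_input} in != "
                f"{self.n_retained} kept + {self.n_excluded} excluded"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"step": self.step, "reason": "retained", "n": self.n_retained}]
        rows += [
            {"step": self.step, "reason": k, "n": v} for k, v in self.excluded.items()
        ]
        return pd.DataFrame(rows)

    def describe(self) -> str:
        lines = [f"[{self.step}] {self.n_input} rows in, {self.n_retained} retained"]
        for k, v in self.excluded.items():
            lines.append(f"  - excluded ({k}): {v}")
        return "\n".join(lines)


def flag_idp_outliers(
    x: pd.DataFrame,
    z_threshold: float = 5.0,
    policy: str = "any",
    max_fraction: float = 0.0,
) -> Tuple[pd.DataFrame, pd.Series, QCReport]:
    """Flag technical outlier cells and derive per-participant exclusions.

    A cell is an outlier when |x - column mean| > z_threshold * column SD
    (sample SD, ddof=1). Columns with zero variance flag nothing (a warning is
    logged). ``policy='any'`` excludes a participant with any flagged cell;
    ``policy='fraction'`` excludes when the flagged share exceeds
    ``max_fraction``.
    """
    if len(x) < 2:
        raise ValueError("outlier flagging needs at least 2 rows")
    vals = x.to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance column(s): no cells flagged there",
            stacklevel=2,
        )
    safe_sd = np.where(zero_var, 1.0, sd)
    with np.errstate(invalid="ignore"):
        mask = np.abs(vals - mean) > z_threshold * safe_sd
    mask[:, zero_var] = False
    mask_df = pd.DataFrame(mask, index=x.index, columns=x.columns)
    frac = mask.mean(axis=1)
    if policy == "any":
        excluded = mask.any(axis=1)
    elif policy == "fraction":
        excluded = frac > max_fraction
    else:
        raise ValueError(f"unknown outlier policy {policy!r}")
    excl = pd.Series(excluded, index=x.index, name="outlier_excluded")
    report = QCReport(
        step="idp_outliers",
        n_input=len(x),
        n_retained=int((~excluded).sum()),
        excluded={"idp_outlier": int(excluded.sum())},
        details=pd.DataFrame(
            {"n_flagged_cells": mask.sum(axis=1), "flagged_fraction": frac},
            index=x.index,
        ),
    )
    report.check_accounting()
    return mask_df, excl, report


def filter_interscan_interval(
    cohort: pd.DataFrame,
    lower_percentile: float = 10.0,
    min_years: float = 2.0,
    isi_col: str = "isi",
) -> Tuple[pd.DataFrame, QCReport]:
    """Drop short-term follow-ups: ISI strictly below the cohort's lower
    percentile or strictly below ``min_years``."""
    isi = cohort[isi_col].to_numpy(dtype=float)
    if np.isnan(isi).any():
        raise ValueError("ISI contains missing values; complete them first")
    cut = np.percentile(isi, lower_percentile) if lower_percentile > 0 else -np.inf
    below_pct = isi < cut
    below_min = isi < min_years
    removed = below_pct | below_min
    kept = cohort.loc[~removed].copy()
    if kept.empty:
        raise ValueError(
            "interval filter removed every row; relax lower_percentile/min_years"
        )
    report = QCReport(
        step="interscan_interval",
        n_input=len(cohort),
        n_retained=len(kept),
        excluded={"isi_short": int(removed.sum())},
        details=pd.DataFrame(
            {
                "criterion": ["below_percentile", "below_min_years", "either"],
                "n": [int(below_pct.sum()), int(below_min.sum()), int(removed.sum())],
            }
        ),
    )
    report.check_accounting()
    return kept, report


def assign_groups(
    cohort: pd.DataFrame,
    onset_date: str = "2020-03-01",
    date_cols: Tuple[str, str] = ("date_t1", "date_t2"),
    covid_col: str = "covid_status",
) -> Tuple[pd.DataFrame, QCReport]:
    """Assign G1/G2 by scan timing relative to the pandemic onset and split
    G1 into G3 (COVID) / G4 (no COVID).

    Rows with both scans after onset are outside the study design and are
    dropped with a logged reason.
    """
    onset = pd.Timestamp(onset_date)
    t1 = pd.to_datetime(cohort[date_cols[0]])
    t2 = pd.to_datetime(cohort[date_cols[1]])
    after1 = t1 >= onset
    after2 = t2 >= onset
    both_after = after1 & after2
    n_drop = int(both_after.sum())
    if n_drop:
        logger.info("assign_groups: dropping %d rows with both scans post-onset", n_drop)
    out = cohort.loc[~both_after].copy()
    a2 = after2.loc[out.index]
    covid = out[covid_col].astype(bool)
    group = np.where(a2, np.where(covid, "G3", "G4"), "G2")
    out["group"] = group
    out["group_main"] = np.where(a2, "G1", "G2")
    report = QCReport(
        step="assign_groups",
        n_input=len(cohort),
        n_retained=len(out),
        excluded={"both_scans_post_onset": n_drop},
    )
    report.check_accounting()
    return out, report


def _smd(x1: np.ndarray, x2: np.ndarray) -> float:
    """Standardised mean difference with pooled SD; 0 when both constant."""
    s1, s2 = x1.std(ddof=1), x2.std(ddof=1)
    pooled = np.sqrt(
        ((len(x1) - 1) * s1**2 + (len(x2) - 1) * s2**2) / (len(x1) + len(x2) - 2)
    )
    diff = x1.mean() - x2.mean()
    if pooled == 0:
        return 0.0 if diff == 0 else np.inf * np.sign(diff)
    return float(diff / pooled)


def balance_table(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    group_pair: Tuple[str, str],
    group_col: str = "group_main",
    smd_flag: float = 0.1,
) -> pd.DataFrame:
    """Per-covariate group means, standardised mean difference and test p.

    Continuous covariates use a two-sample t test; binary ones a chi-square
    (with the same pooled-SD SMD on the 0/1 coding). Covariates with
    |SMD| > ``smd_flag`` are flagged as imbalanced.
    """
    g1 = cohort.loc[cohort[group_col] == group_pair[0]]
    g2 = cohort.loc[cohort[group_col] == group_pair[1]]
    if g1.empty or g2.empty:
        raise ValueError(f"both groups in {group_pair} must be non-empty")
    rows = []
    for cov in covariates:
        x1 = pd.to_numeric(g1[cov], errors="coerce").dropna().to_numpy(dtype=float)
        x2 = pd.to_numeric(g2[cov], errors="coerce").dropna().to_numpy(dtype=float)
        smd = _smd(x1, x2)
        binary = set(np.unique(np.concatenate([x1, x2]))) <= {0.0, 1.0}
        if binary:
            table = np.array(
                [
                    [x1.sum(), len(x1) - x1.sum()],
                    [x2.sum(), len(x2) - x2.sum()],
                ]
            )
            if table[:, 0].sum() in (0, table.sum()) or np.any(table.sum(axis=1) == 0):
                p = 1.0
            else:
                p = float(sps.chi2_contingency(table, correction=False)[1])
        else:
            if x1.std(ddof=1) == 0 and x2.std(ddof=1) == 0:
                p = 1.0 if x1.mean() == x2.mean() else 0.0
            else:
                p = float(sps.ttest_ind(x1, x2, equal_var=True).pvalue)
        rows.append(
            {
                "covariate": cov,
                f"mean_{group_pair[0]}": float(x1.mean()),
                f"mean_{group_pair[1]}": float(x2.mean()),
                "smd": smd,
                "p": p,
                "imbalanced": abs(smd) > smd_flag,
            }
        )
    return pd.DataFrame(rows)


def match_groups(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    group_pair: Tuple[str, str],
    group_col: str = "group_main",
    caliper: float = 0.5,
) -> pd.DataFrame:
    """Optional greedy 1:1 nearest-neighbour matching on standardised
    covariates with a Euclidean caliper. Balance diagnostics, not matching,
    are the primary contract; this helper tightens balance when wanted."""
    g1 = cohort.loc[cohort[group_col] == group_pair[0]]
    g2 = cohort.loc[cohort[group_col] == group_pair[1]]
    z = cohort[list(covariates)].astype(float)
    z = (z - z.mean()) / z.std(ddof=1).replace(0, 1.0)
    z1, z2 = z.loc[g1.index].to_numpy(), z.loc[g2.index].to_numpy()
    used = np.zeros(len(z2), dtype=bool)
    keep1, keep2 = [], []
    for i in range(len(z1)):
        d = np.linalg.norm(z2 - z1[i], axis=1)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= caliper * np.sqrt(len(covariates)):
            used[j] = True
            keep1.append(g1.index[i])
            keep2.append(g2.index[j])
    return cohort.loc[keep1 + keep2].copy()
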