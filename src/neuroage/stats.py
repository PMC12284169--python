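"""Between-group inference: effect sizes, two-sample tests, FDR control,
two-factor two-level permutation ANOVA, Wilson intervals and percentile
stratification.

The permutation ANOVA re-implements the two-factor, two-level design used by
permutation-inference toolboxes: effects are coded in a two-way linear model
(effect coding), and for each tested effect the nuisance terms are partialled
out and the reduced-model residuals are permuted (Freedman–Lane). p-values
use the add-one convention p = (1 + #{F* >= F_obs}) / (1 + n_perm), so they
are never exactly zero and are valid under the null.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cohens_d",
    "two_sample_tests",
    "fdr_bh",
    "permutation_anova_2x2",
    "permutation_ftest",
    "wilson_ci",
    "stratify_by_percentile",
    "deprivation_clock",
    "StatResult",
    "Perm2x2Result",
    "ClockResult",
    "months_days",
]


# ----------------------------------------------------------------------
def cohens_d(x1, x2) -> float:
    """Standardised mean difference with pooled SD.

    d = (mean(x1) - mean(x2)) / s_pooled. Returns 0 when both samples are
    constant and equal; signed infinity when the pooled SD is 0 but the means
    differ.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per sample")
    s1, s2 = x1.var(ddof=1), x2.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    diff = x1.mean() - x2.mean()
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / pooled)


@dataclass
class StatResult:
    """One two-sample comparison (tidy, FDR-ready)."""

    label: str
    kind: str
    n1: int
    n2: int
    estimate: float  # mean difference (x1 - x2)
    cohen_d: float
    statistic: float
    p: float
    p_fdr: float = np.nan
    family: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "kind": self.kind,
            "n1": self.n1,
            "n2": self.n2,
            "estimate": self.estimate,
            "d": self.cohen_d,
            "stat": self.statistic,
            "p": self.p,
            "p_fdr": self.p_fdr,
            "family": self.family,
        }


def two_sample_tests(
    x1,
    x2,
    kind: str = "t",
    label: str = "",
    family: str = "",
    welch: bool = False,
) -> StatResult:
    """Two-sided two-sample test plus Cohen's d.

    ``kind='t'``: Student's pooled-variance t by default (Welch via flag).
    ``kind='mann_whitney'``: exact enumeration for small samples without
    ties (n1 + n2 <= 20), normal approximation with tie correction
    otherwise; an all-tied comparison returns p = 1 by convention.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per sample")
    d = cohens_d(x1, x2)
    est = float(x1.mean() - x2.mean())
    if kind == "t":
        res = sps.ttest_ind(x1, x2, equal_var=not welch)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(stat):  # both samples constant
            stat, p = 0.0, 1.0
    elif kind == "mann_whitney":
        pooled = np.concatenate([x1, x2])
        if np.ptp(pooled) == 0:
            stat, p = float(n1 * n2 / 2.0), 1.0
        else:
            has_ties = len(np.unique(pooled)) < len(pooled)
            method = "exact" if (n1 + n2 <= 20 and not has_ties) else "asymptotic"
            res = sps.mannwhitneyu(x1, x2, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return StatResult(
        label=label,
        kind=kind,
        n1=n1,
        n2=n2,
        estimate=est,
        cohen_d=d,
        statistic=stat,
        p=min(p, 1.0),
        family=family,
    )


def fdr_bh(pvalues: Sequence[float], family: str = "") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(results: List[StatResult]) -> List[StatResult]:
    """Adjust a family of StatResults in place (one family per call)."""
    adj = fdr_bh([r.p for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
    return results


# ----------------------------------------------------------------------
def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


def _partial_f_batch(
    ystar: np.ndarray, h_full: np.ndarray, h_red: np.ndarray, df_resid: int
) -> np.ndarray:
    """F statistics (1 numerator df) for each column of ystar."""
    rss_full = np.einsum("ij,ij->j", ystar - h_full @ ystar, ystar - h_full @ ystar)
    rss_red = np.einsum("ij,ij->j", ystar - h_red @ ystar, ystar - h_red @ ystar)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss_red - rss_full) / (rss_full / df_resid)
    return np.nan_to_num(f, nan=0.0, posinf=np.inf)


def permutation_ftest(
    y: np.ndarray,
    effect: np.ndarray,
    nuisance: Optional[np.ndarray],
    n_perm: int | str = 5000,
    rng: Optional[np.random.Generator] = None,
    scheme: str = "freedman_lane",
) -> Tuple[float, float]:
    """Permutation p for one effect column given nuisance columns.

    Freedman–Lane: residuals of y under the nuisance-only model are permuted
    and added back to the nuisance fit; the partial F of the effect in the
    full model is recomputed for each permutation. With nuisance = intercept
    only this reduces to a plain label permutation of (centred) y.
    ``n_perm='all'`` enumerates every permutation (small n only).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if np.sum((y - y.mean()) ** 2) <= n * np.finfo(float).eps * max(y.mean() ** 2, 1.0):
        # constant response: every permuted statistic ties with the observed one
        return 0.0, 1.0
    effect = np.asarray(effect, dtype=float).reshape(n, -1)
    z = np.ones((n, 1)) if nuisance is None else np.asarray(nuisance, float).reshape(n, -1)
    x_full = np.column_stack([z, effect])
    h_full = _hat(x_full)
    h_red = _hat(z)
    df_resid = n - np.linalg.matrix_rank(x_full)
    f_obs = float(_partial_f_batch(y[:, None], h_full, h_red, df_resid)[0])

    if scheme == "freedman_lane":
        base_fit = h_red @ y
        base_resid = y - base_fit
    elif scheme == "ter_braak":
        # permute residuals of the full model; the permuted statistic is
        # computed on those residuals alone (the observed effect is removed)
        base_fit = np.zeros_like(y)
        base_resid = y - h_full @ y
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    if n_perm == "all":
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        n_perm = int(n_perm)
        if n_perm < 100:
            warnings.warn(
                "fewer than 100 permutations gives very coarse p resolution",
                stacklevel=2,
            )
        if rng is None:
            rng = np.random.default_rng()
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
    ystar = base_fit[:, None] + base_resid[perms].T
    f_perm = _partial_f_batch(ystar, h_full, h_red, df_resid)
    p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + len(perms))
    return f_obs, float(p)


@dataclass
class Perm2x2Result:
    """Two-factor, two-level permutation ANOVA result."""

    f_a: float
    f_b: float
    f_ab: float
    p_a: float
    p_b: float
    p_ab: float
    n_perm: int
    seed: Optional[int]
    scheme: str
    labels: Tuple[str, str] = ("A", "B")

    def to_dict(self) -> dict:
        a, b = self.labels
        return {
            f"F_{a}": self.f_a,
            f"F_{b}": self.f_b,
            f"F_{a}x{b}": self.f_ab,
            f"p_{a}": self.p_a,
            f"p_{b}": self.p_b,
            f"p_{a}x{b}": self.p_ab,
            "n_perm": self.n_perm,
            "scheme": self.scheme,
        }

    def summary(self) -> str:
        a, b = self.labels
        return (
            f"2x2 permutation ANOVA ({self.scheme}, {self.n_perm} permutations)\n"
            f"  main {a}:        F = {self.f_a:8.3f}, p = {self.p_a:.4g}\n"
            f"  main {b}:        F = {self.f_b:8.3f}, p = {self.p_b:.4g}\n"
            f"  interaction:  F = {self.f_ab:8.3f}, p = {self.p_ab:.4g}"
        )


def permutation_anova_2x2(
    y,
    factor_a,
    factor_b,
    n_perm: int = 5000,
    seed: Optional[int] = None,
    scheme: str = "freedman_lane",
    labels: Tuple[str, str] = ("A", "B"),
) -> Perm2x2Result:
    """Permutation p-values for both main effects and the interaction of a
    2x2 design (effect-coded linear model; F statistic per effect).

    For each tested effect the other two terms plus the intercept are treated
    as nuisance and the Freedman–Lane scheme is applied. All four design
    cells must be non-empty.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(factor_a).astype(bool)
    b = np.asarray(factor_b).astype(bool)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("y, factor_a, factor_b must have equal length")
    for va in (False, True):
        for vb in (False, True):
            if not np.any((a == va) & (b == vb)):
                raise ValueError(f"empty design cell ({labels[0]}={va}, {labels[1]}={vb})")
    ac = np.where(a, 1.0, -1.0)
    bc = np.where(b, 1.0, -1.0)
    inter = ac * bc
    ones = np.ones(len(y))
    rng = np.random.default_rng(seed)
    f_a, p_a = permutation_ftest(
        y, ac, np.column_stack([ones, bc, inter]), n_perm, rng, scheme
    )
    f_b, p_b = permutation_ftest(
        y, bc, np.column_stack([ones, ac, inter]), n_perm, rng, scheme
    )
    f_ab, p_ab = permutation_ftest(
        y, inter, np.column_stack([ones, ac, bc]), n_perm, rng, scheme
    )
    return Perm2x2Result(
        f_a=f_a,
        f_b=f_b,
        f_ab=f_ab,
        p_a=p_a,
        p_b=p_b,
        p_ab=p_ab,
        n_perm=int(n_perm),
        seed=seed,
        scheme=scheme,
        labels=labels,
    )


# ----------------------------------------------------------------------
def wilson_ci(p_hat: float, n: int, conf: float = 0.95) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    centre = (p + z^2/2n) / (1 + z^2/n); half-width
    z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n).
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = sps.norm.ppf(1.0 - (1.0 - conf) / 2.0)
    denom = 1.0 + z**2 / n
    centre = (p_hat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2)) / denom
    return (float(centre - half), float(centre + half))


def stratify_by_percentile(
    scores,
    low_pct: float = 30.0,
    high_pct: float = 70.0,
    reference=None,
) -> np.ndarray:
    """'low'/'high'/'unassigned' labels by strict percentile cuts.

    Scores strictly below the ``low_pct`` percentile are 'low', strictly
    above the ``high_pct`` percentile 'high'; everything in between
    (inclusive) is 'unassigned'. Percentile thresholds use the
    linear-interpolation quantile of ``reference`` (defaults to the scores
    themselves). Rank-based, so labels are invariant under monotone
    transforms.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 10:
        raise ValueError("need at least 10 scores to stratify")
    ref = scores if reference is None else np.asarray(reference, dtype=float)
    lo = np.percentile(ref, low_pct)
    hi = np.percentile(ref, high_pct)
    labels = np.full(len(scores), "unassigned", dtype=object)
    if lo == hi:
        warnings.warn(
            "degenerate score distribution: low and high cuts coincide; "
            "all scores unassigned",
            stacklevel=2,
        )
        return labels
    labels[scores < lo] = "low"
    labels[scores > hi] = "high"
    return labels


# ----------------------------------------------------------------------
def months_days(value_years_per_year: float) -> Tuple[int, int]:
    """Render a BAG rate difference as (months, days) of BAG per year.

    Whole months are floored from 12*|v|; the remainder becomes days via
    365.25/12 days per month, rounded to the nearest day.
    """
    total_months = 12.0 * abs(float(value_years_per_year))
    months = int(np.floor(total_months))
    days = int(round((total_months - months) * (365.25 / 12.0)))
    return months, days


@dataclass
class ClockResult:
    """Low-vs-high stratum difference in mean BAG rate ('clock' display)."""

    group: str
    index: str
    diff: float  # years of BAG per year, low stratum minus high stratum
    n_low: int
    n_high: int

    @property
    def display(self) -> str:
        m, d = months_days(self.diff)
        sign = "-" if self.diff < 0 else ""
        return f"{sign}{m} months and {d} days"

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "index": self.index,
            "diff_y_per_y": self.diff,
            "display": self.display,
            "n_low": self.n_low,
            "n_high": self.n_high,
        }


def deprivation_clock(
    records: pd.DataFrame,
    labels,
    group: str = "",
    index: str = "",
    value_col: str = "r_bag",
) -> ClockResult:
    """Difference in mean BAG rate between 'low' and 'high' strata.

    ``labels`` is the output of :func:`stratify_by_percentile`, row-aligned
    with ``records``. The raw difference (years of BAG per year) is always
    retained; ``display`` renders it in months and days.
    """
    labels = np.asarray(labels, dtype=object)
    v = records[value_col].to_numpy(dtype=float)
    low = v[labels == "low"]
    high = v[labels == "high"]
    if len(low) == 0 or len(high) == 0:
        raise ValueError("both strata must be non-empty")
    return ClockResult(
        group=group,
        index=index,
        diff=float(low.mean() - high.mean()),
        n_low=len(low),
        n_high=len(high),
    )
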