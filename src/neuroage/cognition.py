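"""Cognitive change and its relation to the BAG rate.

For timed tests (e.g. trail-making tests, scored in seconds) a positive
percentage change means a longer completion time, i.e. worse performance:

    pct_change  = (score_t2 - score_t1) * 100 / score_t1
    rate_change = (score_t2 - score_t1) / dT      [score units per year]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "cognitive_change",
    "sliding_window_curve",
    "rbag_cognition_association",
    "AssociationResult",
]

logger = logging.getLogger(__name__)


def cognitive_change(
    cohort: pd.DataFrame,
    test: str,
    isi_col: str = "isi",
) -> pd.DataFrame:
    """Per-participant percentage and interval-normalised change for one test.

    Expects columns ``{test}_t1`` and ``{test}_t2``. Rows with missing scores
    are dropped (count logged); rows with a non-positive baseline are rejected
    with a reason column in the log.
    """
    c1, c2 = f"{test}_t1", f"{test}_t2"
    for col in (c1, c2):
        if col not in cohort.columns:
            raise KeyError(f"missing cognitive score column {col!r}")
    df = cohort[["participant_id", c1, c2] + ([isi_col] if isi_col in cohort else [])]
    n0 = len(df)
    df = df.dropna(subset=[c1, c2])
    n_missing = n0 - len(df)
    if n_missing:
        logger.info("%s: dropped %d rows with missing scores", test, n_missing)
    bad = df[c1] <= 0
    if bad.any():
        logger.info("%s: rejected %d rows with non-positive baseline", test, int(bad.sum()))
        df = df.loc[~bad]
    s1 = df[c1].to_numpy(dtype=float)
    s2 = df[c2].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "participant_id": df["participant_id"].to_numpy(),
            "test": test,
            "score_t1": s1,
            "score_t2": s2,
            "pct_change": (s2 - s1) * 100.0 / s1,
        }
    )
    if isi_col in df:
        dt = df[isi_col].to_numpy(dtype=float)
        out["rate_change"] = (s2 - s1) / dt
    return out


def sliding_window_curve(
    x,
    y,
    width: float = 3.0,
    step: Optional[float] = None,
    min_count: int = 5,
) -> pd.DataFrame:
    """Mean and standard error of ``y`` in a sliding window over ``x``.

    Window centres form a regular grid from min(x) to max(x) with
    ``step = width/10`` by default; a point contributes to a window when
    |x - centre| <= width/2. Windows with fewer than ``min_count`` points are
    omitted. Returns columns (center, n, mean, se).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 points")
    if width <= 0:
        raise ValueError("width must be positive")
    step = width / 10.0 if step is None else float(step)
    centers = np.arange(x.min(), x.max() + step / 2.0, step)
    rows = []
    for c in centers:
        sel = np.abs(x - c) <= width / 2.0
        n = int(sel.sum())
        if n < min_count:
            continue
        vals = y[sel]
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append({"center": float(c), "n": n, "mean": float(vals.mean()), "se": se})
    if not rows:
        import warnings

        warnings.warn("all windows under-populated; empty curve", stacklevel=2)
        return pd.DataFrame(columns=["center", "n", "mean", "se"])
    return pd.DataFrame(rows)


@dataclass
class AssociationResult:
    """Full and age-controlled partial correlation of cognitive change with
    the BAG rate within one group."""

    group: str
    test: str
    r_full: float
    p_full: float
    r_partial: float
    p_partial: float
    n: int

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "test": self.test,
            "r_full": self.r_full,
            "p_full": self.p_full,
            "r_partial": self.r_partial,
            "p_partial": self.p_partial,
            "n": self.n,
        }


def _residualise(v: np.ndarray, covar: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), covar])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def rbag_cognition_association(
    records: pd.DataFrame,
    changes: pd.DataFrame,
    group: Optional[str] = None,
    group_col: str = "group_main",
    change_col: str = "pct_change",
) -> AssociationResult:
    """Pearson correlation (full, and partial controlling average age)
    between the BAG rate and cognitive change, joined on participant."""
    df = records if group is None else records.loc[records[group_col] == group]
    m = df.merge(changes, on="participant_id", validate="one_to_one")
    if len(m) < 10:
        raise ValueError("need at least 10 joined records")
    r_bag = m["r_bag"].to_numpy(dtype=float)
    chg = m[change_col].to_numpy(dtype=float)
    if r_bag.std() == 0 or chg.std() == 0:
        return AssociationResult(
            group or "all", str(m["test"].iloc[0]), np.nan, np.nan, np.nan, np.nan, len(m)
        )
    r, p = sps.pearsonr(r_bag, chg)
    age = m["avg_age"].to_numpy(dtype=float)
    rr = _residualise(r_bag, age)
    rc = _residualise(chg, age)
    pr, pp = sps.pearsonr(rr, rc)
    return AssociationResult(
        group=group or "all",
        test=str(m["test"].iloc[0]) if "test" in m else "",
        r_full=float(r),
        p_full=float(p),
        r_partial=float(pr),
        p_partial=float(pp),
        n=len(m),
    )
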