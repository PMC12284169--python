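"""Unbiased brain-age model: deconfounding, SVD reduction, linear age
regression and age-bias correction, with cross-validated performance metrics.

Model
-----
Given an N x M matrix ``X`` of imaging-derived phenotypes (IDPs), confounds
``C`` and chronological ages ``Y``, fitting proceeds as

1. **Deconfounding** — least-squares weights ``W`` mapping ``[1, C]`` to each
   IDP are estimated on the training rows; residualised IDPs are exactly
   uncorrelated with every training confound. The same ``W`` (never a refit)
   is applied to unseen data.
2. **Standardisation** — per-feature z-scoring with training mean/SD (SVD on
   mixed-unit features would otherwise be scale-dominated).
3. **SVD** — the top ``k`` right singular vectors (default 50) give component
   scores ``U``; per-component variance-explained fractions are recorded.
4. **Age regression** — OLS of ``Y`` on ``[1, U]`` yields the predicted brain
   age ``Y_B`` and the raw gap ``delta_raw = Y_B - Y``.
5. **Bias correction** — OLS of ``delta_raw`` on the age basis ``[1, Y, Y^2]``
   (quadratic by default; linear available). The corrected gap
   ``delta = delta_raw - fitted`` is orthogonal to the age basis on the
   training rows at machine precision. For unseen data the training-fitted
   coefficients are evaluated at the new subject's age; nothing is refitted.

The positive corrected gap means an older-appearing brain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BrainAgeModel",
    "fit_deconfounder",
    "fit_svd",
    "fit_bias_correction",
    "BrainAgeResults",
    "CVResult",
    "PerformanceMetrics",
    "cross_validate",
    "performance_metrics",
    "SchemaError",
]

_ORTHO_TOL = 1e-10  # orthogonality assertion tolerance on standardised data


class SchemaError(ValueError):
    """Feature columns of new data do not match the fitted model."""


def _age_basis(y: np.ndarray, kind: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if kind == "quadratic":
        return np.column_stack([np.ones_like(y), y, y**2])
    if kind == "linear":
        return np.column_stack([np.ones_like(y), y])
    raise ValueError(f"unknown bias basis {kind!r}")


def _with_intercept(c: Optional[np.ndarray], n: int) -> np.ndarray:
    if c is None or c.size == 0:
        return np.ones((n, 1))
    c = np.asarray(c, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    return np.column_stack([np.ones(len(c)), c])


def fit_deconfounder(
    x: np.ndarray, confounds: Optional[np.ndarray]
) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares weights mapping [1, confounds] to each IDP column.

    Returns (weights, residuals). Residualised training IDPs are exactly
    uncorrelated with every confound; with an intercept-only design the
    residuals are the mean-centred IDPs. A rank-deficient confound matrix
    falls back to the pseudo-inverse solution with a warning.
    """
    x = np.asarray(x, dtype=float)
    design = _with_intercept(confounds, len(x))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn(
            "rank-deficient confound matrix; using pseudo-inverse", stacklevel=2
        )
    w = np.linalg.pinv(design) @ x
    return w, x - design @ w


def fit_svd(x_std: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-k right singular vectors of the standardised IDP matrix.

    Returns (basis m x k, variance_explained fractions, singular values).
    Raises when k exceeds the numerical rank.
    """
    n, m = x_std.shape
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n, m)={min(n, m)}")
    _, s, vt = np.linalg.svd(x_std, full_matrices=False)
    tol = s.max(initial=0.0) * max(n, m) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if k > rank:
        raise ValueError(
            f"k={k} exceeds the achievable rank {rank} of the input matrix"
        )
    total = float((s**2).sum())
    var = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return vt[:k].T, np.asarray(var, dtype=float), s[:k].copy()


def fit_bias_correction(
    delta_raw: np.ndarray, ages: np.ndarray, basis: str = "quadratic"
) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of the raw gap on the age basis.

    Returns (coefficients, corrected deltas). The corrected deltas are the
    OLS residuals and hence orthogonal to the age basis at machine precision;
    with as many points as basis parameters the fit saturates and the
    corrected deltas are exactly zero.
    """
    ab = _age_basis(np.asarray(ages, dtype=float), basis)
    gamma, *_ = np.linalg.lstsq(ab, np.asarray(delta_raw, dtype=float), rcond=None)
    return gamma, delta_raw - ab @ gamma


class BrainAgeModel:
    """Brain-age model specification for one (sex, tissue) stratum.

    Parameters
    ----------
    idps : array-like or DataFrame, shape (n, m)
        IDP feature matrix. A DataFrame supplies feature names used for
        schema checks at prediction time.
    ages : array-like, shape (n,)
        Chronological ages in years.
    confounds : array-like or DataFrame, shape (n, c), optional
        Nuisance variables. Must not contain age-derived columns.
    k : int
        Number of SVD components retained (default 50).
    bias_basis : {"quadratic", "linear"}
        Age basis of the post-hoc gap correction.
    stratum : tuple, optional
        (sex, tissue) bookkeeping label carried through to records.
    """

    def __init__(
        self,
        idps,
        ages,
        confounds=None,
        *,
        k: int = 50,
        bias_basis: str = "quadratic",
        standardize: bool = True,
        stratum: Optional[Tuple[str, str]] = None,
        feature_names: Optional[Sequence[str]] = None,
        participant_ids: Optional[Sequence[str]] = None,
    ):
        if isinstance(idps, pd.DataFrame):
            feature_names = feature_names or list(idps.columns)
            if participant_ids is None and idps.index.name is not None:
                participant_ids = list(idps.index)
            idps = idps.to_numpy(dtype=float)
        self.exog = np.asarray(idps, dtype=float)
        self.ages = np.asarray(ages, dtype=float)
        if isinstance(confounds, pd.DataFrame):
            confounds = confounds.to_numpy(dtype=float)
        self.confounds = (
            None if confounds is None else np.atleast_2d(np.asarray(confounds, float))
        )
        if self.confounds is not None and self.confounds.shape[0] != len(self.ages):
            self.confounds = self.confounds.T
        n, m = self.exog.shape
        if len(self.ages) != n:
            raise ValueError("idps and ages have mismatched lengths")
        if np.ptp(self.ages) == 0:
            raise ValueError("degenerate age vector: all ages identical")
        if k > min(n, m):
            raise ValueError(f"k={k} exceeds min(n, m)={min(n, m)}")
        if n < k + 3:
            raise ValueError(f"need at least k+3={k + 3} training rows, got {n}")
        self.k = int(k)
        self.bias_basis = bias_basis
        self.standardize = bool(standardize)
        self.stratum = stratum
        self.feature_names = list(feature_names) if feature_names else None
        self.participant_ids = list(participant_ids) if participant_ids else None

    @classmethod
    def from_dataframe(
        cls,
        cohort: pd.DataFrame,
        idps: pd.DataFrame,
        *,
        age_col: str = "age",
        confounds: Optional[pd.DataFrame] = None,
        **kwargs,
    ) -> "BrainAgeModel":
        """Build a model by aligning a cohort table with an IDP table on
        participant id (the IDP index)."""
        cohort = cohort.set_index("participant_id") if "participant_id" in cohort else cohort
        common = idps.index.intersection(cohort.index)
        idps = idps.loc[common]
        ages = cohort.loc[common, age_col].to_numpy(dtype=float)
        conf = confounds.loc[common] if confounds is not None else None
        return cls(idps, ages, conf, participant_ids=list(common), **kwargs)

    def fit(self) -> "BrainAgeResults":
        x, y = self.exog, self.ages
        n, m = x.shape
        # 1) deconfound with training weights
        w, x_res = fit_deconfounder(x, self.confounds)
        # 2) standardise with training parameters
        mu = x_res.mean(axis=0)
        sd = x_res.std(axis=0, ddof=0)
        sd_safe = np.where(sd == 0, 1.0, sd)
        x_std = (x_res - mu) / sd_safe if self.standardize else x_res - mu
        # 3) SVD reduction
        basis, var_explained, singvals = fit_svd(x_std, self.k)
        scores = x_std @ basis
        # 4) age regression on component scores
        reg_design = np.column_stack([np.ones(n), scores])
        beta, *_ = np.linalg.lstsq(reg_design, y, rcond=None)
        y_b = reg_design @ beta
        delta_raw = y_b - y
        # 5) age-bias correction
        gamma, delta = fit_bias_correction(delta_raw, y, self.bias_basis)
        return BrainAgeResults(
            model=self,
            deconfounder_weights=w,
            feature_mean=mu,
            feature_sd=sd_safe,
            svd_basis=basis,
            singular_values=singvals,
            variance_explained=var_explained,
            age_coefficients=beta,
            bias_coefficients=gamma,
            train_predictions=y_b,
            train_delta_raw=delta_raw,
            train_delta=delta,
        )


@dataclass
class BrainAgeResults:
    """Fitted brain-age model artefact.

    Exposes the fitted weights, the training brain-age-gap records, and
    :meth:`predict` for unseen data using training weights only.
    """

    model: BrainAgeModel
    deconfounder_weights: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    svd_basis: np.ndarray
    singular_values: np.ndarray
    variance_explained: np.ndarray
    age_coefficients: np.ndarray
    bias_coefficients: np.ndarray
    train_predictions: np.ndarray
    train_delta_raw: np.ndarray
    train_delta: np.ndarray

    FORMAT_VERSION = 1

    # ------------------------------------------------------------------
    def predict(
        self,
        idps,
        ages,
        confounds=None,
        *,
        session: str = "t1",
        participant_ids: Optional[Sequence[str]] = None,
        refit_bias: bool = False,
    ) -> pd.DataFrame:
        """Brain-age-gap records for unseen data.

        Applies the training deconfounder weights, standardisation, SVD basis
        and regression coefficients; the training bias-correction curve is
        evaluated at each subject's age. With ``refit_bias=True`` the
        correction is re-estimated on the new data instead (off by default;
        it makes the gap exactly orthogonal to age in the new sample at the
        cost of using test-set information).
        """
        if isinstance(idps, pd.DataFrame):
            if self.model.feature_names is not None:
                missing = set(self.model.feature_names) - set(idps.columns)
                extra = set(idps.columns) - set(self.model.feature_names)
                if missing or extra:
                    raise SchemaError(
                        f"feature mismatch: missing={sorted(missing)[:5]}, "
                        f"unexpected={sorted(extra)[:5]}"
                    )
                idps = idps[self.model.feature_names]
            if participant_ids is None:
                participant_ids = list(idps.index)
            idps = idps.to_numpy(dtype=float)
        x = np.asarray(idps, dtype=float)
        if x.shape[1] != self.svd_basis.shape[0]:
            raise SchemaError(
                f"expected {self.svd_basis.shape[0]} features, got {x.shape[1]}"
            )
        y = np.asarray(ages, dtype=float)
        if np.isnan(x).any():
            raise SchemaError("missing IDP cells; drop or exclude those rows first")
        if isinstance(confounds, pd.DataFrame):
            confounds = confounds.to_numpy(dtype=float)
        design = _with_intercept(
            None if confounds is None else np.asarray(confounds, float), len(x)
        )
        if design.shape[1] != self.deconfounder_weights.shape[0]:
            raise SchemaError(
                f"expected {self.deconfounder_weights.shape[0] - 1} confounds, "
                f"got {design.shape[1] - 1}"
            )
        x_res = x - design @ self.deconfounder_weights
        x_std = (x_res - self.feature_mean) / self.feature_sd
        if not self.model.standardize:
            x_std = x_res - self.feature_mean
        scores = x_std @ self.svd_basis
        y_b = np.column_stack([np.ones(len(x)), scores]) @ self.age_coefficients
        delta_raw = y_b - y
        ab = _age_basis(y, self.model.bias_basis)
        if refit_bias:
            gamma, *_ = np.linalg.lstsq(ab, delta_raw, rcond=None)
        else:
            gamma = self.bias_coefficients
        delta = delta_raw - ab @ gamma
        out = pd.DataFrame(
            {
                "participant_id": (
                    participant_ids
                    if participant_ids is not None
                    else [f"S{i:06d}" for i in range(len(x))]
                ),
                "session": session,
                "Y": y,
                "Y_B": y_b,
                "delta_raw": delta_raw,
                "delta": delta,
            }
        )
        if self.model.stratum is not None:
            out["sex"], out["tissue"] = self.model.stratum
        return out

    # ------------------------------------------------------------------
    def training_records(self, session: str = "t1") -> pd.DataFrame:
        ids = self.model.participant_ids or [
            f"S{i:06d}" for i in range(len(self.model.ages))
        ]
        out = pd.DataFrame(
            {
                "participant_id": ids,
                "session": session,
                "Y": self.model.ages,
                "Y_B": self.train_predictions,
                "delta_raw": self.train_delta_raw,
                "delta": self.train_delta,
            }
        )
        if self.model.stratum is not None:
            out["sex"], out["tissue"] = self.model.stratum
        return out

    def orthogonality(self) -> Dict[str, float]:
        """|corr(corrected training delta, age-basis column)| diagnostics."""
        y = self.model.ages
        d = self.train_delta
        out = {}
        cols = {"Y": y, "Y2": y**2}
        if self.model.bias_basis == "linear":
            cols.pop("Y2")
        for name, v in cols.items():
            out[name] = float(abs(np.corrcoef(d, v)[0, 1])) if d.std() > 0 else 0.0
        return out

    def summary(self) -> str:
        m = self.model
        perf = performance_metrics(self.train_predictions, m.ages)
        lines = [
            "Brain-age model (unbiased delta)",
            "=" * 48,
            f"stratum:           {m.stratum or '-'}",
            f"n training rows:   {len(m.ages)}",
            f"n features:        {m.exog.shape[1]}",
            f"SVD components:    {m.k}",
            f"variance explained: {self.variance_explained.sum():.3f}",
            f"bias basis:        {m.bias_basis}",
            f"in-sample r:       {perf.r:.4f}",
            f"in-sample MAE:     {perf.mae:.3f} y",
            f"mean corrected delta: {self.train_delta.mean():+.2e} y",
        ]
        for name, v in self.orthogonality().items():
            lines.append(f"|corr(delta, {name})|: {v:.2e}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialise to a single portable JSON file (version-stamped)."""
        payload = {
            "format_version": self.FORMAT_VERSION,
            "k": self.model.k,
            "bias_basis": self.model.bias_basis,
            "standardize": self.model.standardize,
            "stratum": list(self.model.stratum) if self.model.stratum else None,
            "feature_names": self.model.feature_names,
            "deconfounder_weights": self.deconfounder_weights.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "svd_basis": self.svd_basis.tolist(),
            "singular_values": self.singular_values.tolist(),
            "variance_explained": self.variance_explained.tolist(),
            "age_coefficients": self.age_coefficients.tolist(),
            "bias_coefficients": self.bias_coefficients.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "BrainAgeResults":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError("unsupported model artefact version")
        basis = np.asarray(payload["svd_basis"], dtype=float)
        m, k = basis.shape
        # reconstruct a minimal model shell able to predict
        shell = BrainAgeModel.__new__(BrainAgeModel)
        shell.k = k
        shell.bias_basis = payload["bias_basis"]
        shell.standardize = payload["standardize"]
        shell.stratum = tuple(payload["stratum"]) if payload["stratum"] else None
        shell.feature_names = payload["feature_names"]
        shell.participant_ids = None
        shell.ages = np.empty(0)
        shell.exog = np.empty((0, m))
        shell.confounds = None
        return cls(
            model=shell,
            deconfounder_weights=np.asarray(payload["deconfounder_weights"], float),
            feature_mean=np.asarray(payload["feature_mean"], float),
            feature_sd=np.asarray(payload["feature_sd"], float),
            svd_basis=basis,
            singular_values=np.asarray(payload["singular_values"], float),
            variance_explained=np.asarray(payload["variance_explained"], float),
            age_coefficients=np.asarray(payload["age_coefficients"], float),
            bias_coefficients=np.asarray(payload["bias_coefficients"], float),
            train_predictions=np.empty(0),
            train_delta_raw=np.empty(0),
            train_delta=np.empty(0),
        )


# ----------------------------------------------------------------------
@dataclass
class PerformanceMetrics:
    r: float
    r_ci: Tuple[float, float]
    mae: float
    n: int


def performance_metrics(pred, true) -> PerformanceMetrics:
    """Pearson r (with Fisher-z 95% CI) and MAE between predicted and true
    ages. r is NaN when either vector has zero variance."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if len(pred) != len(true):
        raise ValueError("pred and true must have equal length")
    if len(pred) < 3:
        raise ValueError("need at least 3 pairs")
    mae = float(np.mean(np.abs(pred - true)))
    if pred.std() == 0 or true.std() == 0:
        return PerformanceMetrics(np.nan, (np.nan, np.nan), mae, len(pred))
    r = float(np.corrcoef(pred, true)[0, 1])
    if abs(r) < 1.0 and len(pred) > 3:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(len(pred) - 3)
        ci = (float(np.tanh(z - 1.959963984540054 * se)),
              float(np.tanh(z + 1.959963984540054 * se)))
    else:
        ci = (r, r)
    return PerformanceMetrics(r, ci, mae, len(pred))


# ----------------------------------------------------------------------
@dataclass
class CVResult:
    """Cross-validated out-of-fold performance over repeated fold draws."""

    per_repetition: pd.DataFrame  # columns: repetition, r, mae
    oof_predictions: np.ndarray  # repeats x n raw out-of-fold predicted ages
    fold_assignments: np.ndarray  # repeats x n fold indices
    seed: Optional[int]
    folds: int
    repeats: int

    @property
    def r_mean(self) -> float:
        return float(self.per_repetition["r"].mean())

    @property
    def r_sd(self) -> float:
        return float(self.per_repetition["r"].std(ddof=1)) if self.repeats > 1 else 0.0

    @property
    def mae_mean(self) -> float:
        return float(self.per_repetition["mae"].mean())

    @property
    def mae_sd(self) -> float:
        return float(self.per_repetition["mae"].std(ddof=1)) if self.repeats > 1 else 0.0

    def summary(self) -> str:
        return (
            f"{self.folds}-fold CV x {self.repeats} repetitions: "
            f"r = {self.r_mean:.4f} +/- {self.r_sd:.4f}, "
            f"MAE = {self.mae_mean:.3f} +/- {self.mae_sd:.3f} y"
        )


def _fold_assignment(
    ages: np.ndarray, folds: int, rng: np.random.Generator, stratify: bool
) -> np.ndarray:
    n = len(ages)
    assign = np.empty(n, dtype=int)
    if stratify:
        # stratify by age decile so every fold spans the age range
        deciles = np.clip(
            np.searchsorted(np.percentile(ages, np.arange(10, 100, 10)), ages), 0, 9
        )
        start = 0
        for d in range(10):
            idx = np.flatnonzero(deciles == d)
            rng.shuffle(idx)
            assign[idx] = (np.arange(len(idx)) + start) % folds
            start += len(idx)
    else:
        perm = rng.permutation(n)
        assign[perm] = np.arange(n) % folds
    return assign


def cross_validate(
    idps,
    ages,
    confounds=None,
    *,
    k: int = 50,
    folds: int = 20,
    repeats: int = 100,
    seed: Optional[int] = None,
    bias_basis: str = "quadratic",
    stratify_by_age: bool = True,
) -> CVResult:
    """Repeated k-fold cross-validation of the full fitting chain.

    Every fold refits deconfounder, standardisation, SVD and regressions on
    the remaining folds and predicts the held-out fold, so no training
    information leaks into the out-of-fold predictions. Per repetition,
    Pearson r and MAE are computed on the pooled raw out-of-fold predicted
    ages, then averaged across repetitions.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if isinstance(idps, pd.DataFrame):
        idps = idps.to_numpy(dtype=float)
    x = np.asarray(idps, dtype=float)
    y = np.asarray(ages, dtype=float)
    if len(x) < folds:
        raise ValueError("need at least one row per fold")
    c = None
    if confounds is not None:
        if isinstance(confounds, pd.DataFrame):
            confounds = confounds.to_numpy(dtype=float)
        c = np.asarray(confounds, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    oof = np.empty((repeats, n))
    assignments = np.empty((repeats, n), dtype=int)
    rows = []
    for rep in range(repeats):
        assign = _fold_assignment(y, folds, rng, stratify_by_age)
        assignments[rep] = assign
        pred = np.empty(n)
        for f in range(folds):
            test = assign == f
            train = ~test
            res = BrainAgeModel(
                x[train],
                y[train],
                None if c is None else c[train],
                k=k,
                bias_basis=bias_basis,
            ).fit()
            pred[test] = res.predict(
                x[test], y[test], None if c is None else c[test]
            )["Y_B"].to_numpy()
        oof[rep] = pred
        perf = performance_metrics(pred, y)
        rows.append({"repetition": rep, "r": perf.r, "mae": perf.mae})
    return CVResult(
        per_repetition=pd.DataFrame(rows),
        oof_predictions=oof,
        fold_assignments=assignments,
        seed=seed,
        folds=folds,
        repeats=repeats,
    )
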