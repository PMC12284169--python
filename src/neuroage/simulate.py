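"""Synthetic cohort generator for longitudinal brain-age analyses.

Emulates the statistical structure the downstream pipeline assumes: a
cross-sectional training cohort and a paired-scan longitudinal cohort, with
imaging-derived phenotypes (IDPs) built as a linear-Gaussian low-rank model

    X = (brain-age-driven low-rank signal) + (confound contamination) + noise,

where "brain age" is chronological age plus a stable per-subject deviation
(the true brain-age gap, BAG). Longitudinal subjects carry a true BAG rate
composed of a common drift, an age-dependent term, an injectable
Pandemic-group offset, a deprivation interaction, and subject-level noise.
Ground truth is recorded so parameter recovery can be tested end to end.

All quantities are reproducible from ``SimulationConfig.seed`` via the
documented per-stage seeding scheme in :mod:`neuroage.config`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig, stage_rng

__all__ = [
    "IDPMatrix",
    "GroundTruth",
    "SEXES",
    "TISSUES",
    "generate_training_cohort",
    "generate_longitudinal_cohort",
    "generate_cognitive_scores",
]

logger = logging.getLogger(__name__)

SEXES = ("F", "M")
TISSUES = ("GM", "WM")

_ONSET_FALLBACK = "2020-03-01"


@dataclass
class IDPMatrix:
    """Participants x features table for one (sex, tissue) stratum and session.

    ``data`` is indexed by participant id; ``confounds`` is row-aligned with
    ``data`` and carries the generic nuisance variables the deconfounder uses.
    """

    data: pd.DataFrame
    confounds: pd.DataFrame
    sex: str
    tissue: str
    session: str = "t1"

    @property
    def feature_names(self):
        return list(self.data.columns)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="participant_id")


@dataclass
class GroundTruth:
    """Per-participant injected truth for the longitudinal cohort."""

    data: pd.DataFrame
    injected_effect: float
    injected_interaction: float

    def realised_injected_difference(self) -> float:
        """Mean injected (Pandemic - Control) offset actually drawn."""
        pand = self.data.loc[self.data["arm"] == "pandemic", "injected_offset"]
        ctrl = self.data.loc[self.data["arm"] == "control", "injected_offset"]
        return float(pand.mean() - ctrl.mean())

    def realised_rbag_difference(self) -> float:
        """Mean realised (Pandemic - Control) difference in true BAG rate."""
        pand = self.data.loc[self.data["arm"] == "pandemic", "true_rbag"]
        ctrl = self.data.loc[self.data["arm"] == "control", "true_rbag"]
        return float(pand.mean() - ctrl.mean())

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def _truncated_normal(rng, mean, sd, lo, hi, n):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _stratum_loadings(config: SimulationConfig, sex: str, tissue: str):
    """Fixed generative loadings per stratum, derived from the master seed only.

    Shared between training and longitudinal generation so a model trained on
    the former applies to the latter.
    """
    rng = stage_rng(
        config.seed, "loadings", extra=(SEXES.index(sex), TISSUES.index(tissue))
    )
    q, m, c = config.n_signal_components, config.n_idps, config.n_confounds
    loadings = rng.standard_normal((q, m)) / max(np.sqrt(q), 1.0)
    age_weights = rng.uniform(0.5, 1.5, size=q) if q else np.empty(0)
    conf_loadings = rng.standard_normal((c, m)) if c else np.empty((0, m))
    return loadings, age_weights, conf_loadings


def _idp_block(
    config: SimulationConfig,
    brain_age: np.ndarray,
    latent: np.ndarray,
    confounds: np.ndarray,
    sex: str,
    tissue: str,
    rng_noise: np.random.Generator,
) -> np.ndarray:
    """Assemble one IDP matrix from brain age, stable latents and confounds."""
    loadings, age_weights, conf_loadings = _stratum_loadings(config, sex, tissue)
    q = config.n_signal_components
    b_z = (brain_age - config.age_mean) / config.age_sd
    if q:
        scores = b_z[:, None] * age_weights[None, :]
        scores = scores + config.component_noise_sd * latent[:, :q]
        signal = scores @ loadings
        age_part = (b_z[:, None] * age_weights[None, :]) @ loadings
        signal_sd = float(age_part.std())
    else:
        signal = np.zeros((len(brain_age), config.n_idps))
        signal_sd = 0.0
    x = signal.copy()
    if config.n_confounds:
        x += config.confound_strength * (confounds @ conf_loadings)
    if np.isinf(config.signal_to_noise):
        noise_sd = 0.0
    elif config.signal_to_noise > 0 and signal_sd > 0:
        noise_sd = signal_sd / config.signal_to_noise
    else:
        # no age-driven signal (or SNR 0): unit measurement noise
        noise_sd = 1.0
    if noise_sd > 0:
        x += noise_sd * rng_noise.standard_normal(x.shape)
    return x


def _feature_frame(x, ids, tissue):
    cols = [f"{tissue}_idp_{j:04d}" for j in range(x.shape[1])]
    return pd.DataFrame(x, index=pd.Index(ids, name="participant_id"), columns=cols)


def generate_training_cohort(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], IDPMatrix]]:
    """Cross-sectional training cohort with one IDP matrix per sex x tissue.

    Returns the cohort table (one row per participant; ages Gaussian with the
    configured mean/SD truncated to ``age_range``; ``true_bag`` column records
    the stable deviation used to drive the IDPs) and a dict keyed by
    ``(sex, tissue)`` of :class:`IDPMatrix` with row-aligned confounds.
    """
    rng = stage_rng(config.seed, "training_cohort")
    n = config.n_train
    ids = [f"T{i:06d}" for i in range(n)]
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    age = _truncated_normal(
        rng, config.age_mean, config.age_sd, *config.age_range, n
    )
    true_bag = rng.normal(0.0, config.bag_sd, size=n)
    confounds = rng.standard_normal((n, config.n_confounds))
    latent = rng.standard_normal((n, max(config.n_signal_components, 1)))

    cohort = pd.DataFrame(
        {
            "participant_id": ids,
            "sex": sex,
            "age": age,
            "true_bag": true_bag,
            "group": "training",
        }
    )
    conf_cols = [f"conf_{j}" for j in range(config.n_confounds)]

    rng_noise = stage_rng(config.seed, "training_idps")
    idps: Dict[Tuple[str, str], IDPMatrix] = {}
    for s in SEXES:
        rows = np.flatnonzero(sex == s)
        for t in TISSUES:
            x = _idp_block(
                config,
                age[rows] + true_bag[rows],
                latent[rows],
                confounds[rows],
                s,
                t,
                rng_noise,
            )
            idps[(s, t)] = IDPMatrix(
                data=_feature_frame(x, [ids[i] for i in rows], t),
                confounds=pd.DataFrame(
                    confounds[rows],
                    index=pd.Index([ids[i] for i in rows], name="participant_id"),
                    columns=conf_cols,
                ),
                sex=s,
                tissue=t,
                session="t1",
            )
    return cohort, idps


def _decimal_year_to_date(y: np.ndarray) -> pd.Series:
    base = pd.Timestamp("1970-01-01")
    return pd.Series(
        [base + pd.Timedelta(days=(v - 1970.0) * 365.25) for v in y]
    ).dt.strftime("%Y-%m-%d")


def generate_longitudinal_cohort(
    config: SimulationConfig,
    replicate: int = 0,
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str, str], IDPMatrix], GroundTruth]:
    """Paired-scan cohort with injected group effects on the true BAG rate.

    Each participant receives two sessions. The Control arm is scanned twice
    before the pandemic onset with a narrow inter-scan interval (ISI); the
    Pandemic arm straddles the onset with a wider ISI spread. The true BAG at
    the second scan encodes a common ageing drift, an age-dependent term, the
    configured Pandemic offset (``true_rbag_effect``), and an extra offset for
    deprived Pandemic participants (``deprivation_interaction``).

    ``replicate`` mixes an extra integer into the cohort/IDP stage seeds so
    that independent cohort draws can be generated under the same generative
    loadings (and hence scored by the same trained model).
    """
    rng = stage_rng(config.seed, "longitudinal_cohort", extra=(replicate,))
    n_per = config.n_longitudinal
    n = 2 * n_per
    ids = [f"L{i:06d}" for i in range(n)]
    arm = np.array(["pandemic"] * n_per + ["control"] * n_per)
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    age_t1 = _truncated_normal(
        rng, config.age_mean, config.age_sd, *config.age_range, n
    )

    isi = np.empty(n)
    lo_c, hi_c = config.isi_range_control
    lo_p, hi_p = config.isi_range_pandemic
    ctrl = arm == "control"
    pand = ~ctrl
    # Control: narrow, roughly Gaussian around the range midpoint
    isi[ctrl] = _truncated_normal(
        rng, (lo_c + hi_c) / 2, (hi_c - lo_c) / 4 or 0.1, lo_c, hi_c, int(ctrl.sum())
    )
    # Pandemic: uniform over a wider range (lockdown-interrupted scheduling)
    isi[pand] = rng.uniform(lo_p, hi_p, size=int(pand.sum()))
    if isi.max() < 2.0:
        import warnings

        warnings.warn(
            "all inter-scan intervals fall below the 2-year follow-up filter",
            stacklevel=2,
        )
    age_t2 = age_t1 + isi

    onset = pd.Timestamp(config.pandemic_onset or _ONSET_FALLBACK)
    onset_year = onset.year + (onset.dayofyear - 1) / 365.25
    t1_year = np.empty(n)
    t1_year[ctrl] = rng.uniform(2015.0, onset_year - hi_c - 0.1, size=int(ctrl.sum()))
    # Pandemic arm: first scan before onset, second after
    offset_before = rng.uniform(0.1, np.maximum(isi[pand] - 0.1, 0.11))
    t1_year[pand] = onset_year - offset_before
    t2_year = t1_year + isi

    covid = np.zeros(n, dtype=bool)
    covid[pand] = rng.random(int(pand.sum())) < config.covid_fraction

    # attainment-style indices: lower score = more deprived
    dep_cols = ["dep_housing", "dep_health", "dep_employment", "dep_income", "dep_education"]
    deprivation = rng.standard_normal((n, len(dep_cols)))
    # "deprived" for the injected interaction: bottom 30% of the employment index
    emp = deprivation[:, dep_cols.index("dep_employment")]
    deprived = emp < np.percentile(emp, 30)

    avg_age = (age_t1 + age_t2) / 2
    injected = np.where(pand, config.true_rbag_effect, 0.0) + np.where(
        pand & deprived, config.deprivation_interaction, 0.0
    )
    true_rbag = (
        config.baseline_drift
        + config.age_drift_slope * (avg_age - config.age_mean)
        + injected
        + rng.normal(0.0, config.rbag_noise_sd, size=n)
    )
    delta_t1 = rng.normal(0.0, config.bag_sd, size=n)
    delta_t2 = delta_t1 + true_rbag * isi

    bmi = rng.normal(26.5, 4.0, size=n)
    household = rng.integers(1, 6, size=n).astype(float)
    confounds = {
        "t1": rng.standard_normal((n, config.n_confounds)),
        "t2": rng.standard_normal((n, config.n_confounds)),
    }
    latent = rng.standard_normal((n, max(config.n_signal_components, 1)))

    cohort = pd.DataFrame(
        {
            "participant_id": ids,
            "sex": sex,
            "age_t1": age_t1,
            "age_t2": age_t2,
            "isi": isi,
            "date_t1": _decimal_year_to_date(t1_year).values,
            "date_t2": _decimal_year_to_date(t2_year).values,
            "covid_status": covid,
            "bmi": bmi,
            "household_size": household,
            "eligible": True,
        }
    )
    for j, c in enumerate(dep_cols):
        cohort[c] = deprivation[:, j]

    conf_cols = [f"conf_{j}" for j in range(config.n_confounds)]
    rng_noise = stage_rng(config.seed, "longitudinal_idps", extra=(replicate,))
    idps: Dict[Tuple[str, str, str], IDPMatrix] = {}
    delta_by_session = {"t1": delta_t1, "t2": delta_t2}
    age_by_session = {"t1": age_t1, "t2": age_t2}
    for session in ("t1", "t2"):
        for s in SEXES:
            rows = np.flatnonzero(sex == s)
            for t in TISSUES:
                b = age_by_session[session][rows] + delta_by_session[session][rows]
                x = _idp_block(
                    config, b, latent[rows], confounds[session][rows], s, t, rng_noise
                )
                idps[(s, t, session)] = IDPMatrix(
                    data=_feature_frame(x, [ids[i] for i in rows], t),
                    confounds=pd.DataFrame(
                        confounds[session][rows],
                        index=pd.Index(
                            [ids[i] for i in rows], name="participant_id"
                        ),
                        columns=conf_cols,
                    ),
                    sex=s,
                    tissue=t,
                    session=session,
                )

    truth = GroundTruth(
        data=pd.DataFrame(
            {
                "participant_id": ids,
                "arm": arm,
                "covid_status": covid,
                "deprived": deprived,
                "delta_t1": delta_t1,
                "delta_t2": delta_t2,
                "isi": isi,
                "true_rbag": true_rbag,
                "injected_offset": injected,
            }
        ),
        injected_effect=config.true_rbag_effect,
        injected_interaction=config.deprivation_interaction,
    )
    return cohort, idps, truth


_COG_BASELINES = {"TMT-A": (35.0, 10.0), "TMT-B": (65.0, 20.0)}


def generate_cognitive_scores(
    cohort: pd.DataFrame,
    config: SimulationConfig,
    truth: GroundTruth,
    tests: Tuple[str, ...] = ("TMT-A", "TMT-B"),
    replicate: int = 0,
) -> pd.DataFrame:
    """Attach per-test baseline and follow-up completion times (seconds).

    Follow-up = baseline * (1 + [drift + coupling * true R_BAG * infected]/100
    + noise/100); the coupling applies only to infected participants. Scores
    are strictly positive; non-positive draws are resampled and counted.
    """
    rng = stage_rng(config.seed, "cognition", extra=(replicate,))
    out = cohort.copy()
    t = truth.data.set_index("participant_id").loc[out["participant_id"]]
    infected = t["covid_status"].to_numpy().astype(float)
    true_rbag = t["true_rbag"].to_numpy()
    n = len(out)
    for test in tests:
        mu, sd = _COG_BASELINES.get(test, (50.0, 15.0))
        base = _truncated_normal(rng, mu, sd, 5.0, np.inf, n)
        mult = (
            1.0
            + (
                config.cognition_drift
                + config.cognition_coupling * true_rbag * infected
            )
            / 100.0
            + (config.cognition_noise / 100.0) * rng.standard_normal(n)
        )
        follow = base * mult
        resampled = 0
        bad = follow <= 0
        while bad.any():
            resampled += int(bad.sum())
            mult_new = (
                1.0
                + (
                    config.cognition_drift
                    + config.cognition_coupling * true_rbag[bad] * infected[bad]
                )
                / 100.0
                + (config.cognition_noise / 100.0) * rng.standard_normal(int(bad.sum()))
            )
            follow[bad] = base[bad] * mult_new
            bad = follow <= 0
        if resampled:
            logger.info("%s: resampled %d non-positive follow-up scores", test, resampled)
        out[f"{test}_t1"] = base
        out[f"{test}_t2"] = follow
    return out
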