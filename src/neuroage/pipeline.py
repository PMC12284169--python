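"""End-to-end pipeline: simulate -> QC -> fit -> predict -> longitudinal
rates -> group statistics -> cognition, with per-stage CSV outputs and a
reproducibility manifest.

Stage order and row accounting follow the study design: group assignment by
scan timing, interval filtering, per-session outlier exclusion, sex- and
tissue-stratified model fits on the training cohort, prediction of both
sessions of the unseen cohort with training weights only, and group-level
inference on the per-participant BAG rates (sexes pooled within tissue).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .brainage import BrainAgeModel, BrainAgeResults, CVResult, cross_validate
from .cognition import cognitive_change, rbag_cognition_association, sliding_window_curve
from .config import RunConfig, config_hash, stage_rng
from .longitudinal import (
    age_effect_regression,
    compute_rbag,
    reproducibility_stats,
    years_to_months,
)
from .qc import assign_groups, filter_interscan_interval, flag_idp_outliers
from .simulate import (
    SEXES,
    TISSUES,
    generate_cognitive_scores,
    generate_longitudinal_cohort,
    generate_training_cohort,
)
from .stats import (
    apply_fdr,
    deprivation_clock,
    permutation_anova_2x2,
    stratify_by_percentile,
    two_sample_tests,
)

logger = logging.getLogger(__name__)

DEPRIVATION_INDICES = (
    "dep_housing",
    "dep_health",
    "dep_employment",
    "dep_income",
    "dep_education",
)

PAIRWISE = (("G1", "G2"), ("G3", "G2"), ("G4", "G2"), ("G3", "G4"))


@dataclass
class PipelineResult:
    """All stage outputs of one run, plus the manifest."""

    out_dir: Path
    manifest: dict
    models: Dict[Tuple[str, str], BrainAgeResults]
    cv: Dict[Tuple[str, str], CVResult]
    cohort: pd.DataFrame
    truth: "object"
    rbag: Dict[str, pd.DataFrame]  # per tissue
    comparisons: pd.DataFrame
    age_effects: pd.DataFrame
    perm_tests: pd.DataFrame
    clocks: pd.DataFrame
    reproducibility: pd.DataFrame
    cognition_stats: pd.DataFrame
    associations: pd.DataFrame
    summary_text: str

    def summary(self) -> str:
        return self.summary_text


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stat_rows(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def run_pipeline(config: RunConfig, out_dir: Optional[str] = None) -> PipelineResult:
    """Execute every stage and write CSV outputs plus ``manifest.json``.

    Re-running with an identical config reproduces identical outputs and an
    identical manifest hash.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    # ---------------- stage 1: simulate ----------------
    logger.info("stage simulate: training n=%d, longitudinal n=%d/group",
                sim.n_train, sim.n_longitudinal)
    train_cohort, train_idps = generate_training_cohort(sim)
    lon_cohort, lon_idps, truth = generate_longitudinal_cohort(sim)
    lon_cohort = generate_cognitive_scores(lon_cohort, sim, truth)

    # ---------------- stage 2: QC ----------------
    lon_cohort, rep_groups = assign_groups(lon_cohort, config.onset_date)
    lon_cohort, rep_isi = filter_interscan_interval(
        lon_cohort, config.isi_lower_pct, config.min_isi_years
    )
    qc_rows = [rep_groups.to_frame(), rep_isi.to_frame()]

    # training outliers: drop flagged participant-sessions per stratum
    train_keep: Dict[Tuple[str, str], pd.Index] = {}
    for key, idp in train_idps.items():
        _, excl, rep = flag_idp_outliers(idp.data, config.z_threshold)
        train_keep[key] = idp.data.index[~excl.to_numpy()]
        qc_rows.append(rep.to_frame().assign(stratum="-".join(key)))
    # longitudinal outliers: exclude a participant flagged in any session
    lon_flagged: set = set()
    for (s, t, session), idp in lon_idps.items():
        _, excl, rep = flag_idp_outliers(idp.data, config.z_threshold)
        lon_flagged |= set(idp.data.index[excl.to_numpy()])
        qc_rows.append(rep.to_frame().assign(stratum=f"{s}-{t}-{session}"))
    if lon_flagged:
        lon_cohort = lon_cohort.loc[~lon_cohort["participant_id"].isin(lon_flagged)]
    retained = set(lon_cohort["participant_id"])

    # ---------------- stage 3: fit per (sex, tissue) ----------------
    models: Dict[Tuple[str, str], BrainAgeResults] = {}
    cv: Dict[Tuple[str, str], CVResult] = {}
    train_idx = train_cohort.set_index("participant_id")
    cv_seed_rng = stage_rng(config.seed, "crossval")
    for (s, t), idp in train_idps.items():
        keep = train_keep[(s, t)]
        x = idp.data.loc[keep]
        c = idp.confounds.loc[keep]
        ages = train_idx.loc[keep, "age"].to_numpy(dtype=float)
        model = BrainAgeModel(
            x,
            ages,
            c,
            k=config.k,
            bias_basis=config.bias_basis,
            stratum=(s, t),
            participant_ids=list(keep),
        )
        models[(s, t)] = model.fit()
        cv[(s, t)] = cross_validate(
            x,
            ages,
            c,
            k=config.k,
            folds=config.folds,
            repeats=config.repeats,
            seed=int(cv_seed_rng.integers(2**31 - 1)),
            bias_basis=config.bias_basis,
        )
        logger.info("fitted %s-%s: %s", s, t, cv[(s, t)].summary())

    # ---------------- stage 4: predict + BAG rates ----------------
    lon_idx = lon_cohort.set_index("participant_id")
    rbag: Dict[str, pd.DataFrame] = {}
    repro_rows = []
    for t in TISSUES:
        recs = {"t1": [], "t2": []}
        for session in ("t1", "t2"):
            for s in SEXES:
                idp = lon_idps[(s, t, session)]
                ids = [i for i in idp.data.index if i in retained]
                if not ids:
                    continue
                recs[session].append(
                    models[(s, t)].predict(
                        idp.data.loc[ids],
                        lon_idx.loc[ids, f"age_{session}"].to_numpy(dtype=float),
                        idp.confounds.loc[ids],
                        session=session,
                        participant_ids=ids,
                    )
                )
        bag1 = pd.concat(recs["t1"], ignore_index=True)
        bag2 = pd.concat(recs["t2"], ignore_index=True)
        rbag[t] = compute_rbag(bag1, bag2, lon_cohort)
        for g in ("G1", "G2"):
            sub = rbag[t].loc[rbag[t]["group_main"] == g]
            st = reproducibility_stats(
                sub["yb_t1"], sub["yb_t2"], sub["age_t1"], sub["age_t2"]
            )
            repro_rows.append(
                {
                    "tissue": t,
                    "group": g,
                    "pearson_r": st.pearson_r,
                    "icc": st.icc,
                    "icc_lo": st.icc_ci[0],
                    "icc_hi": st.icc_ci[1],
                    "partial_r": st.partial_r,
                    "n": st.n,
                }
            )
    reproducibility = pd.DataFrame(repro_rows)

    # ---------------- stage 5: group statistics ----------------
    perm_rng = stage_rng(config.seed, "permutation")
    comp_rows, age_rows, perm_rows, clock_rows = [], [], [], []
    for t in TISSUES:
        df = rbag[t]
        fam = []
        for g1, g2 in PAIRWISE:
            x1 = df.loc[df["group"].isin(_expand(g1)), "r_bag"]
            x2 = df.loc[df["group"].isin(_expand(g2)), "r_bag"]
            fam.append(
                two_sample_tests(
                    x1, x2, kind="t", label=f"{g1}_vs_{g2}", family=f"rbag_{t}"
                )
            )
        # baseline BAG comparability at the first scan (Mann-Whitney)
        b1 = df.loc[df["group_main"] == "G1", "delta_t1"]
        b2 = df.loc[df["group_main"] == "G2", "delta_t1"]
        fam.append(
            two_sample_tests(
                b1, b2, kind="mann_whitney", label="baseline_G1_vs_G2",
                family=f"rbag_{t}",
            )
        )
        comp_rows.append(_stat_rows(apply_fdr(fam)).assign(tissue=t))

        for g in ("G1", "G2", "G3", "G4"):
            sub = df.loc[df["group"].isin(_expand(g))]
            if len(sub) >= 10:
                res = age_effect_regression(sub.assign(group_main=g), group=g)
                age_rows.append(
                    {
                        "tissue": t,
                        "group": g,
                        "slope_y_per_y_per_year": res.slope,
                        "slope_days_per_year": res.slope_days,
                        "ci_lo": res.ci[0],
                        "ci_hi": res.ci[1],
                        "p": res.p,
                        "n": res.n,
                    }
                )

        pandemic = (df["group_main"] == "G1").to_numpy()
        male = (df["sex"] == "M").to_numpy()
        res = permutation_anova_2x2(
            df["r_bag"].to_numpy(),
            pandemic,
            male,
            n_perm=config.n_perm,
            seed=int(perm_rng.integers(2**31 - 1)),
            labels=("pandemic", "male"),
        )
        perm_rows.append({"tissue": t, "factor": "sex", **res.to_dict()})

        for index in DEPRIVATION_INDICES:
            labels = stratify_by_percentile(
                df[index].to_numpy(), config.low_pct, config.high_pct
            )
            # attainment-style scores: the 'low' stratum is the deprived one
            for g, gname in (("G1", "pandemic"), ("G2", "control")):
                sel = (df["group_main"] == g).to_numpy()
                sub = df.loc[sel]
                sub_labels = labels[sel]
                if (sub_labels == "low").sum() and (sub_labels == "high").sum():
                    clock = deprivation_clock(sub, sub_labels, group=gname, index=index)
                    clock_rows.append({"tissue": t, **clock.to_dict()})
            assigned = labels != "unassigned"
            res = permutation_anova_2x2(
                df.loc[assigned, "r_bag"].to_numpy(),
                pandemic[assigned],
                (labels[assigned] == "low"),
                n_perm=config.n_perm,
                seed=int(perm_rng.integers(2**31 - 1)),
                labels=("pandemic", "deprived"),
            )
            perm_rows.append({"tissue": t, "factor": index, **res.to_dict()})

    comparisons = pd.concat(comp_rows, ignore_index=True)
    age_effects = pd.DataFrame(age_rows)
    perm_tests = pd.DataFrame(perm_rows)
    clocks = pd.DataFrame(clock_rows)

    # ---------------- stage 6: cognition ----------------
    cog_rows, assoc_rows = [], []
    curves: Dict[str, pd.DataFrame] = {}
    for test in ("TMT-A", "TMT-B"):
        changes = cognitive_change(lon_cohort, test)
        fam = []
        for g1, g2 in (("G3", "G2"), ("G3", "G4"), ("G4", "G2")):
            c1 = changes.merge(
                lon_cohort.loc[lon_cohort["group"].isin(_expand(g1)), ["participant_id"]]
            )["pct_change"]
            c2 = changes.merge(
                lon_cohort.loc[lon_cohort["group"].isin(_expand(g2)), ["participant_id"]]
            )["pct_change"]
            fam.append(
                two_sample_tests(
                    c1, c2, kind="t", label=f"{g1}_vs_{g2}", family=f"cognition_{test}"
                )
            )
        cog_rows.append(_stat_rows(apply_fdr(fam)).assign(test=test))
        for t in TISSUES:
            for g in ("G2", "G3", "G4"):
                df = rbag[t].loc[rbag[t]["group"].isin(_expand(g))]
                try:
                    a = rbag_cognition_association(
                        df.assign(group_main=g), changes, group=g
                    )
                except ValueError:
                    continue
                assoc_rows.append({"tissue": t, **a.to_dict()})
                merged = df.merge(changes, on="participant_id")
                curves[f"{test}_{t}_{g}"] = sliding_window_curve(
                    merged["r_bag"].to_numpy(),
                    merged["pct_change"].to_numpy(),
                    width=3.0,
                )
    cognition_stats = pd.concat(cog_rows, ignore_index=True)
    associations = pd.DataFrame(assoc_rows)

    # ---------------- stage 7: outputs + manifest ----------------
    files = {
        "cohort_training.csv": train_cohort,
        "cohort_longitudinal.csv": lon_cohort,
        "ground_truth.csv": truth.data,
        "qc_report.csv": pd.concat(qc_rows, ignore_index=True),
        "reproducibility.csv": reproducibility,
        "comparisons.csv": comparisons,
        "age_effects.csv": age_effects,
        "perm_tests.csv": perm_tests,
        "deprivation_clocks.csv": clocks,
        "cognition_stats.csv": cognition_stats,
        "cognition_associations.csv": associations,
    }
    for t in TISSUES:
        files[f"rbag_{t}.csv"] = rbag[t]
    for name, curve in curves.items():
        files[f"curve_{name}.csv"] = curve
    for name, df in files.items():
        df.to_csv(out / name, index=False)
    for key, res in models.items():
        res.save(out / f"model_{key[0]}_{key[1]}.json")

    summary_text = _summary_text(config, truth, cv, rbag, comparisons, age_effects,
                                 perm_tests, clocks, reproducibility, cognition_stats)
    (out / "summary.txt").write_text(summary_text)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config_hash(config.to_dict()),
        "seed": config.seed,
        "rows": {
            "training": len(train_cohort),
            "longitudinal_in": 2 * sim.n_longitudinal,
            "longitudinal_retained": len(lon_cohort),
        },
        "outputs": {name: _sha256(out / name) for name in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        out_dir=out,
        manifest=manifest,
        models=models,
        cv=cv,
        cohort=lon_cohort,
        truth=truth,
        rbag=rbag,
        comparisons=comparisons,
        age_effects=age_effects,
        perm_tests=perm_tests,
        clocks=clocks,
        reproducibility=reproducibility,
        cognition_stats=cognition_stats,
        associations=associations,
        summary_text=summary_text,
    )


def _expand(g: str) -> Tuple[str, ...]:
    """G1 is the union of its COVID subgroups in the group column."""
    return ("G3", "G4") if g == "G1" else (g,)


def _summary_text(config, truth, cv, rbag, comparisons, age_effects, perm_tests,
                  clocks, reproducibility, cognition_stats) -> str:
    lines = ["Longitudinal brain-age pipeline summary", "=" * 48]
    for key, c in cv.items():
        lines.append(f"model {key[0]}-{key[1]}: {c.summary()}")
    lines.append("")
    for t, df in rbag.items():
        g1 = df.loc[df["group_main"] == "G1"]
        g2 = df.loc[df["group_main"] == "G2"]
        diff = g1["r_bag"].mean() - g2["r_bag"].mean()
        d2 = g1["delta_t2"].mean() - g2["delta_t2"].mean()
        lines.append(
            f"[{t}] Pandemic-Control R_BAG difference: {diff:+.3f} y/y "
            f"({float(years_to_months(diff)):+.2f} months/year); "
            f"BAG difference at t2: {float(years_to_months(d2)):+.2f} months"
        )
    lines.append(
        f"ground truth: injected effect {truth.injected_effect:+.3f} y/y, "
        f"realised {truth.realised_rbag_difference():+.3f} y/y"
    )
    lines.append("")
    lines.append("pairwise comparisons (t tests, BH-FDR within tissue):")
    for _, r in comparisons.iterrows():
        lines.append(
            f"  [{r['tissue']}] {r['label']}: d = {r['d']:+.3f}, "
            f"p_fdr = {r['p_fdr']:.3g}"
        )
    if len(age_effects):
        lines.append("age-effect slopes (days of BAG per year, per year of age):")
        for _, r in age_effects.iterrows():
            lines.append(
                f"  [{r['tissue']}] {r['group']}: {r['slope_days_per_year']:+.1f} d/y, "
                f"p = {r['p']:.3g}"
            )
    lines.append("2x2 permutation tests (pandemic x factor):")
    for _, r in perm_tests.iterrows():
        second = "male" if r["factor"] == "sex" else "deprived"
        lines.append(
            f"  [{r['tissue']}] {r['factor']}: p_pandemic = {r['p_pandemic']:.4g}, "
            f"p_factor = {r[f'p_{second}']:.4g}, "
            f"p_interaction = {r[f'p_pandemicx{second}']:.4g}"
        )
    if len(clocks):
        lines.append("deprivation clocks (low-minus-high mean R_BAG):")
        for _, r in clocks.iterrows():
            lines.append(
                f"  [{r['tissue']}] {r['group']} {r['index']}: {r['display']}"
            )
    lines.append("scan-rescan reproducibility:")
    for _, r in reproducibility.iterrows():
        lines.append(
            f"  [{r['tissue']}] {r['group']}: r = {r['pearson_r']:.3f}, "
            f"ICC(2,1) = {r['icc']:.3f} [{r['icc_lo']:.3f}, {r['icc_hi']:.3f}], "
            f"partial r = {r['partial_r']:.3f}"
        )
    lines.append("cognitive change (percentage, t tests with BH-FDR):")
    for _, r in cognition_stats.iterrows():
        lines.append(
            f"  [{r['test']}] {r['label']}: diff = {r['estimate']:+.2f}%, "
            f"p_fdr = {r['p_fdr']:.3g}"
        )
    return "\n".join(lines) + "\n"
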