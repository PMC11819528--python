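"""End-to-end orchestration: clean -> classify -> split -> model.

Every stage reads and writes delimited text, so any stage can be
re-run in isolation; all randomness flows from the config seed and a
rerun with the same config reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .anthropometry import classify_severity, derive_flags
from .cleaning import CleaningReport, clean_visits
from .lms import LMSTable, synthetic_lms_table
from .multinomial import fit_multinomial, model_metrics, vif_screen, wald_test
from .outcomes import FlowCounts, build_analysis_set, classify_all
from .response import (
    compute_gains_frame, first_month_no_gain, split_non_responders,
)
from .simulate import SimConfig, simulate_cohort
from .trajectory import weekly_curve_table

logger = logging.getLogger(__name__)

TRAJECTORY_OUTCOMES = {
    "muac_mm": True, "weight_kg": True,   # age-adjusted, as in the study models
    "whz": False, "waz": False, "haz": False, "height_cm": False,
}


@dataclass
class GroupComparison:
    variable: str
    kind: str                      # "categorical" | "continuous"
    statistic: float
    p_value: float
    summary: pd.DataFrame          # counts (%) or median (IQR) per group
    warning: str | None = None


def compare_groups(df: pd.DataFrame, variable: str, group_col: str,
                   kind: str | None = None) -> GroupComparison:
    """Chi-squared test for categorical variables, Kruskal-Wallis for
    continuous; medians and IQRs (or counts and %) reported alongside.
    """
    sub = df[[variable, group_col]].dropna()
    if sub[group_col].nunique() < 2:
        raise ValueError("need at least 2 groups")
    if kind is None:
        kind = (
            "categorical"
            if sub[variable].dtype == object or sub[variable].dtype == bool
            or sub[variable].nunique() <= 2
            else "continuous"
        )
    warning = None
    if kind == "categorical":
        table = pd.crosstab(sub[variable], sub[group_col])
        if table.to_numpy().min() == 0 or (
            stats.contingency.expected_freq(table.to_numpy()) < 1
        ).any():
            warning = "expected cell count < 1; chi-square approximation unreliable"
        stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        summary = table.copy()
    else:
        groups = [g[variable].to_numpy(dtype=float) for _, g in sub.groupby(group_col)]
        stat, p = stats.kruskal(*groups)
        summary = sub.groupby(group_col)[variable].agg(
            median="median",
            q1=lambda v: v.quantile(0.25),
            q3=lambda v: v.quantile(0.75),
        )
    return GroupComparison(variable, kind, float(stat), float(p), summary, warning)


@dataclass
class RunReport:
    outdir: Path
    flow: FlowCounts
    cleaning: CleaningReport
    thresholds: dict
    categories: pd.DataFrame
    descriptive: pd.DataFrame
    model_summary: dict
    provenance: dict = field(default_factory=dict)


def _age_category(age_months):
    return pd.cut(
        age_months, bins=[6, 12, 24, 60], right=False,
        labels=["6-11", "12-23", "24-59"], include_lowest=True,
    )


def build_covariates(visits: pd.DataFrame, analysis: pd.DataFrame) -> pd.DataFrame:
    """Per-child admission covariates for the multinomial model: sex,
    age category, admission MUAC/WHZ/WAZ categories, any morbidity,
    and the no-gain-in-first-month flags."""
    rows = []
    for child_id, sub in visits.groupby("child_id", sort=False):
        adm = sub.iloc[0]
        muac = adm["muac_mm"]
        rows.append(
            {
                "child_id": child_id,
                "sex": adm["sex"],
                "age_cat": None if pd.isna(adm["age_months"])
                else str(_age_category(pd.Series([adm["age_months"]]))[0]),
                "muac_cat": None if pd.isna(muac) else (
                    "<110" if muac < 110 else "110-114" if muac < 115
                    else "115-119" if muac < 120 else ">=120"
                ),
                "whz_lt_m3": None if pd.isna(adm["whz"]) else bool(adm["whz"] < -3),
                "waz_lt_m3": None if pd.isna(adm["waz"]) else bool(adm["waz"] < -3),
                "morbidity_any": bool(sub["morbidity"].any()),
                "no_muac_gain_1mo": first_month_no_gain(sub, "muac_mm"),
                "no_weight_gain_1mo": first_month_no_gain(sub, "weight_kg"),
            }
        )
    cov = pd.DataFrame(rows)
    return cov[cov["child_id"].isin(analysis["child_id"])].reset_index(drop=True)


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    visits: pd.DataFrame,
    labels: pd.DataFrame,
    outdir,
    reference: LMSTable | None = None,
    split_indicator: str = "muac",
    min_los_weeks: int = 12,
    fence_k: float = 1.5,
    fit_trajectories: bool = True,
    fit_model: bool = True,
    make_plots: bool = False,
    seed: int | None = None,
) -> RunReport:
    """Run clean -> classify -> split (-> trajectories -> model) and
    persist every stage artefact under ``outdir`` as delimited text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = reference if reference is not None else LMSTable(synthetic_lms_table())

    logger.info("stage: clean (%d visits)", len(visits))
    cleaned, creport = clean_visits(visits, ref, fence_k=fence_k)
    _write(cleaned, outdir / "visits_clean.tsv")
    _write(creport.to_frame(), outdir / "cleaning_counts.tsv")
    _write(creport.audit_frame(), outdir / "cleaning_audit.tsv")

    logger.info("stage: classify")
    outcomes = classify_all(cleaned, labels, min_los_weeks=min_los_weeks)
    analysis, flow = build_analysis_set(outcomes)
    _write(outcomes, outdir / "exit_outcomes.tsv")
    _write(flow.to_frame(), outdir / "flow_counts.tsv")

    logger.info("stage: split")
    analysis_visits = cleaned[cleaned["child_id"].isin(analysis["child_id"])]
    gains = compute_gains_frame(analysis_visits)
    categories, thr = split_non_responders(
        gains, analysis[["child_id", "final_label"]], indicator=split_indicator
    )
    _write(gains, outdir / "gains.tsv")
    _write(categories, outdir / "response_categories.tsv")
    thresholds = {"indicator": thr.indicator, "q1": thr.q1, "n_used": thr.n_used}

    cat_col = categories[["child_id", "response_category"]]
    covariates = build_covariates(analysis_visits, analysis).merge(cat_col, on="child_id")

    desc_rows = []
    merged = covariates.merge(gains, on="child_id")
    for var, kind in [
        ("sex", "categorical"), ("morbidity_any", "categorical"),
        ("delta_muac", "continuous"), ("delta_weight", "continuous"),
        ("rate", "continuous"), ("los_weeks", "continuous"),
    ]:
        try:
            cmp_res = compare_groups(merged, var, "response_category", kind)
            desc_rows.append(
                {"variable": var, "kind": kind, "statistic": cmp_res.statistic,
                 "p_value": cmp_res.p_value}
            )
        except ValueError:
            pass
    descriptive = pd.DataFrame(desc_rows)
    _write(descriptive, outdir / "group_comparisons.tsv")

    if fit_trajectories:
        logger.info("stage: trajectories")
        traj_data = analysis_visits.merge(cat_col, on="child_id")
        traj_data = traj_data[traj_data["response_category"] != "unassigned"].copy()
        dates = pd.to_datetime(traj_data["visit_date"])
        adm = traj_data.groupby("child_id")["visit_date"].transform("min")
        traj_data["week"] = (dates - pd.to_datetime(adm)).dt.days // 7
        traj_data["group"] = traj_data["response_category"]
        adm_age = traj_data.groupby("child_id")["age_months"].transform("first")
        traj_data["age_adm_months"] = adm_age
        curve_tables = {}
        for outcome, adjust in TRAJECTORY_OUTCOMES.items():
            curves = weekly_curve_table(traj_data, outcome, adjust_age=adjust)
            _write(curves, outdir / f"curves_{outcome}.tsv")
            curve_tables[outcome] = curves
        if make_plots:
            from .plots import plot_weekly_curves

            plot_weekly_curves(curve_tables, outdir / "curves_panel.png")

    model_summary = {}
    if fit_model:
        logger.info("stage: model")
        model_df = covariates[covariates["response_category"] != "unassigned"].dropna()
        X = model_df[
            ["sex", "age_cat", "muac_cat", "whz_lt_m3", "waz_lt_m3",
             "morbidity_any", "no_muac_gain_1mo", "no_weight_gain_1mo"]
        ]
        y = model_df["response_category"]
        if y.nunique() == 3 and len(model_df) > 40:
            vif = vif_screen(X)
            fit = fit_multinomial(y, X)
            metrics = model_metrics(fit, X, y)
            ors = fit.odds_ratios()
            wald = {
                v: wald_test(fit, v)[2] for v in X.columns if fit.converged
            }
            _write(ors, outdir / "model_odds_ratios.tsv")
            _write(vif.rename_axis("term").reset_index(), outdir / "model_vif.tsv")
            if make_plots:
                from .plots import forest_plot

                forest_plot(ors, outdir / "forest_plot.png")
            model_summary = {
                "n": len(model_df),
                "converged": fit.converged,
                "accuracy": metrics.accuracy,
                "auc": metrics.auc,
                "wald_p": wald,
                "max_vif": float(vif.max()),
            }
        else:
            logger.warning("model stage skipped: too few children or categories")

    provenance = {
        "package_version": __version__,
        "seed": seed,
        "n_input_children": flow.n_input,
        "config_hash": hashlib.sha256(
            json.dumps(
                {"split_indicator": split_indicator, "min_los_weeks": min_los_weeks,
                 "fence_k": fence_k, "seed": seed},
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return RunReport(
        outdir=outdir, flow=flow, cleaning=creport, thresholds=thresholds,
        categories=categories, descriptive=descriptive,
        model_summary=model_summary, provenance=provenance,
    )


def simulate_to_files(config: SimConfig, outdir) -> tuple[Path, Path, Path]:
    """Simulate a cohort and write visits / labels / truth sidecar files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    vpath, lpath, tpath = (
        outdir / "visits.tsv", outdir / "labels.tsv", outdir / "truth.tsv"
    )
    _write(cohort.visits, vpath)
    _write(cohort.labels, lpath)
    _write(cohort.truth, tpath)
    return vpath, lpath, tpath
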