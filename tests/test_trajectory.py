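"""Penalized-spline group smoother: exactness, recovery, intervals."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from cmamgrowth.trajectory import (
    fit_group_curves, predict_weekly_means, weekly_curve_table,
)


def linear_panel(n_per_group=20, weeks=13, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    lines = {"A": (100.0, 2.0), "B": (90.0, 1.0)}
    for g, (a, b) in lines.items():
        for i in range(n_per_group):
            for w in range(weeks):
                rows.append((f"{g}{i}", w, g, a + b * w + rng.normal(0, noise)))
    return pd.DataFrame(rows, columns=["child_id", "week", "group", "y"]), lines


class TestExactness:
    def test_noiseless_linear_recovered(self):
        d, lines = linear_panel()
        fit = fit_group_curves(d, "y")
        pred = predict_weekly_means(fit, np.arange(13))
        for g, (a, b) in lines.items():
            p = pred[pred["group"] == g]
            err = np.abs(p["mean"].to_numpy() - (a + b * p["week"].to_numpy()))
            assert err.max() < 1e-3

    def test_infinite_smoothing_gives_straight_line(self):
        rng = np.random.default_rng(1)
        d, _ = linear_panel(noise=0.0)
        d["y"] = d["y"] + rng.normal(0, 1.0, len(d))  # noisy around the lines
        fit = fit_group_curves(d, "y", subject_effects=False, lambda_smooth=1e10)
        pred = predict_weekly_means(fit, np.arange(13))
        for g in ["A", "B"]:
            sub = d[d["group"] == g]
            slope, intercept = np.polyfit(sub["week"], sub["y"], 1)
            p = pred[pred["group"] == g]
            err = np.abs(p["mean"].to_numpy() - (intercept + slope * p["week"].to_numpy()))
            assert err.max() < 1e-3

    def test_near_zero_smoothing_interpolates_group_week_means(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(30):
            for w in range(8):
                rows.append((f"c{i}", w, "A", np.sin(w) * 5 + rng.normal(0, 1)))
        d = pd.DataFrame(rows, columns=["child_id", "week", "group", "y"])
        fit = fit_group_curves(d, "y", subject_effects=False,
                               lambda_smooth=1e-8, n_interior_knots=4)
        pred = predict_weekly_means(fit, np.arange(8))
        means = d.groupby("week")["y"].mean()
        assert np.abs(pred["mean"].to_numpy() - means.to_numpy()).max() < 0.05

    def test_all_zero_outcome(self):
        d, _ = linear_panel()
        d["y"] = 0.0
        pred = weekly_curve_table(d, "y")
        assert np.abs(pred["mean"]).max() < 1e-8
        assert np.allclose(pred["ci_low"], -pred["ci_high"], atol=1e-8)


class TestRecovery:
    def test_saturating_curve_rmse_below_1mm(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(300):
            b = rng.normal(0, 1.5)   # between-child variation
            for w in range(13):
                mu = 125 - 15 * np.exp(-w / 4)
                rows.append((f"c{i}", w, "g", mu + b + rng.normal(0, 2)))
        d = pd.DataFrame(rows, columns=["child_id", "week", "group", "y"])
        pred = weekly_curve_table(d, "y")
        true = 125 - 15 * np.exp(-pred["week"].to_numpy() / 4)
        rmse = np.sqrt(np.mean((pred["mean"].to_numpy() - true) ** 2))
        assert rmse < 1.0

    def test_identical_groups_within_joint_ci(self):
        rng = np.random.default_rng(8)
        rows = []
        for g in ["A", "B"]:
            for i in range(200):
                b = rng.normal(0, 1.0)
                for w in range(13):
                    mu = 115 + 8 * (1 - np.exp(-w / 5))
                    rows.append((f"{g}{i}", w, g, mu + b + rng.normal(0, 2)))
        d = pd.DataFrame(rows, columns=["child_id", "week", "group", "y"])
        pred = weekly_curve_table(d, "y")
        a = pred[pred["group"] == "A"].set_index("week")
        b = pred[pred["group"] == "B"].set_index("week")
        gap = (a["mean"] - b["mean"]).abs()
        half_widths = (a["ci_high"] - a["ci_low"] + b["ci_high"] - b["ci_low"]) / 2
        assert (gap < half_widths).all()

    def test_subject_effect_inert_when_children_identical(self):
        d, _ = linear_panel(noise=0.0)
        d["y"] = d["y"] + np.sin(d["week"])   # same curve for every child
        with_re = fit_group_curves(d, "y", subject_effects=True, lambda_smooth=1.0)
        without = fit_group_curves(d, "y", subject_effects=False, lambda_smooth=1.0)
        pa = predict_weekly_means(with_re, np.arange(13))
        pb = predict_weekly_means(without, np.arange(13))
        assert np.abs(pa["mean"].to_numpy() - pb["mean"].to_numpy()).max() < 1e-6

    def test_ci_width_shrinks_with_n(self):
        def width(n, seed):
            rng = np.random.default_rng(seed)
            rows = []
            for i in range(n):
                for w in range(10):
                    rows.append((f"c{i}", w, "g",
                                 100 + w + rng.normal(0, 3)))
            d = pd.DataFrame(rows, columns=["child_id", "week", "group", "y"])
            p = weekly_curve_table(d, "y", subject_effects=False)
            return (p["ci_high"] - p["ci_low"]).mean()

        assert width(400, 3) < width(50, 3)


class TestInterface:
    def test_extrapolation_is_an_error(self):
        d, _ = linear_panel()
        fit = fit_group_curves(d, "y")
        with pytest.raises(ValueError):
            predict_weekly_means(fit, [15])

    def test_age_adjustment_evaluated_at_reference(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(100):
            age = rng.uniform(6, 40)
            for w in range(10):
                rows.append((f"c{i}", w, "g", 100 + w + 0.5 * age + rng.normal(0, 1), age))
        d = pd.DataFrame(rows, columns=["child_id", "week", "group", "y", "age_adm_months"])
        fit = fit_group_curves(d, "y", adjust_age=True)
        assert fit.age_coef == pytest.approx(0.5, abs=0.05)
        p_young = predict_weekly_means(fit, [5], reference_age=10.0)
        p_old = predict_weekly_means(fit, [5], reference_age=30.0)
        assert p_old["mean"].iloc[0] - p_young["mean"].iloc[0] == pytest.approx(10.0, abs=1.0)

    def test_basis_reduction_warns(self):
        d, _ = linear_panel(weeks=5)
        with pytest.warns(UserWarning, match="reduced spline basis"):
            fit_group_curves(d, "y", n_interior_knots=10)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_against_mgcv_reference(tmp_path):
    """Independent oracle: mgcv's penalized-spline GAM with child random
    intercepts should produce near-identical weekly population curves."""
    rng = np.random.default_rng(42)
    rows = []
    for g, (start, lift) in {"rec": (118.0, 10.0), "nr": (110.0, 4.0)}.items():
        for i in range(60):
            b = rng.normal(0, 1.5)
            for w in range(11):
                mu = start + lift * (1 - np.exp(-w / 4))
                rows.append((f"{g}{i}", w, g, mu + b + rng.normal(0, 2)))
    d = pd.DataFrame(rows, columns=["child_id", "week", "group", "y"])
    fit = fit_group_curves(d, "y", method="reml")
    mine = predict_weekly_means(fit, np.arange(11)).sort_values(["group", "week"])

    csv = tmp_path / "d.csv"
    d.to_csv(csv, index=False)
    out = tmp_path / "pred.csv"
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        library(mgcv)
        d <- read.csv("{csv}")
        d$group <- factor(d$group); d$child_id <- factor(d$child_id)
        m <- gam(y ~ group + s(week, by=group, k=10) + s(child_id, bs="re"),
                 data=d, method="REML")
        grid <- expand.grid(week=0:10, group=levels(d$group))
        grid$child_id <- d$child_id[1]
        p <- predict(m, newdata=grid, exclude="s(child_id)", newdata.guaranteed=TRUE)
        grid$mean <- p
        write.csv(grid[, c("group","week","mean")], "{out}", row.names=FALSE)
    """))
    res = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
    assert res.returncode == 0, res.stderr
    theirs = pd.read_csv(out).sort_values(["group", "week"])
    diff = mine["mean"].to_numpy() - theirs["mean"].to_numpy()
    assert np.sqrt(np.mean(diff**2)) < 0.5   # outcome units (mm)
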