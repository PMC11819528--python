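"""Three-layer data-quality pass for longitudinal anthropometry.

1. per-visit plausibility bounds (height 60-120 cm, MUAC 70-200 mm,
   weight 3.5-40 kg; out-of-bound values set missing);
2. visit-to-visit longitudinal consistency (a height decrease, or a
   weekly change beyond +/-1.5 kg weight, +/-15 mm MUAC, +1.5 cm
   height, blanks the later value; thresholds scale linearly with the
   inter-visit gap in weeks, capped at 4);
3. pooled boxplot (Tukey-fence) outlier flagging of each z-score
   indicator, computed on the post-consistency pool.

Measurement rules run before the pooled z-score rule so that a single
full pass is idempotent: a second pass sees exactly the measurement set
the first pass converged to, recomputes the same z-scores, and hence
the same fences.  Visits recording no anthropometry at all are dropped
up front.  Nothing is imputed; every blanked cell is recorded in a
:class:`CleaningReport` audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anthropometry import ZSCORE_COLUMNS, ZSCORE_INPUT, add_zscores
from .lms import LMSTable

PLAUSIBILITY_BOUNDS = {
    "height_cm": (60.0, 120.0),
    "muac_mm": (70.0, 200.0),
    "weight_kg": (3.5, 40.0),
}

#: maximum plausible change per week of inter-visit gap
WEEKLY_DELTA_LIMITS = {"weight_kg": 1.5, "muac_mm": 15.0, "height_cm": 1.5}

MEASUREMENT_COLUMNS = ["weight_kg", "height_cm", "muac_mm"]

RULES = ("bounds", "negative_height", "weekly_delta", "z_outlier")


@dataclass
class CleaningReport:
    """Counts of blanked values by rule and variable, plus an audit trail."""

    n_empty_visits_dropped: int = 0
    counts: dict = field(default_factory=dict)  # (rule, variable) -> count
    audit: list = field(default_factory=list)   # dicts: child_id, visit_date, variable, rule
    fences: dict = field(default_factory=dict)  # z column -> (low, high)

    def add(self, rule: str, variable: str, entries) -> None:
        self.counts[(rule, variable)] = self.counts.get((rule, variable), 0) + len(entries)
        self.audit.extend(
            {"child_id": c, "visit_date": d, "variable": variable, "rule": rule}
            for c, d in entries
        )

    @property
    def total_flagged(self) -> int:
        return sum(self.counts.values())

    def by_rule(self) -> dict:
        out: dict[str, int] = {}
        for (rule, _), n in self.counts.items():
            out[rule] = out.get(rule, 0) + n
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": r, "variable": v, "n_flagged": n}
            for (r, v), n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["rule", "variable", "n_flagged"])

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.audit, columns=["child_id", "visit_date", "variable", "rule"]
        )


def drop_empty_visits(visits: pd.DataFrame):
    """Remove visits with no anthropometric measurement at all."""
    empty = visits[MEASUREMENT_COLUMNS].isna().all(axis=1)
    return visits.loc[~empty].copy(), int(empty.sum())


def flag_implausible_values(visits: pd.DataFrame, report: CleaningReport | None = None):
    """Blank measurements outside the per-visit plausibility bounds."""
    out = visits.copy()
    report = report if report is not None else CleaningReport()
    for var, (lo, hi) in PLAUSIBILITY_BOUNDS.items():
        vals = out[var]
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        if bad.any():
            report.add("bounds", var, list(zip(out.loc[bad, "child_id"], out.loc[bad, "visit_date"])))
            out.loc[bad, var] = np.nan
    return out, report


def tukey_fences(values, k: float = 1.5):
    """Boxplot fences (Q1 - k*IQR, Q3 + k*IQR) of the non-missing pool."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("all values missing")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def flag_zscore_outliers(values, k: float = 1.5):
    """Mask of values outside the pooled Tukey fences (NaN -> False)."""
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).any():
        raise ValueError("all values missing")
    if np.isfinite(v).sum() < 4:
        raise ValueError("need at least 4 non-missing values for boxplot fences")
    lo, hi = tukey_fences(v, k)
    with np.errstate(invalid="ignore"):
        return (v < lo) | (v > hi)


def enforce_longitudinal_consistency(
    visits: pd.DataFrame,
    report: CleaningReport | None = None,
    gap_cap_weeks: float = 4.0,
):
    """Blank later values that are inconsistent with the previous visit.

    Within each child (visits sorted by date) and for each measurement:
    any height decrease blanks the later height; a change beyond the
    weekly limit times the gap in weeks (min 1, capped at
    ``gap_cap_weeks``) blanks the later value.  Comparisons skip
    already-missing values, so the surviving series is self-consistent
    and a second pass flags nothing.
    """
    report = report if report is not None else CleaningReport()
    out = visits.copy()
    for child_id, idx in out.groupby("child_id", sort=False).groups.items():
        sub = out.loc[idx]
        dates = pd.to_datetime(sub["visit_date"])
        if dates.is_monotonic_increasing is False:
            raise ValueError(f"visits for child {child_id!r} are not sorted by date")
        days = (dates - dates.iloc[0]).dt.days.to_numpy()
        for var, per_week in WEEKLY_DELTA_LIMITS.items():
            vals = sub[var].to_numpy(dtype=float)
            last_val, last_day = np.nan, np.nan
            for i in range(len(vals)):
                v = vals[i]
                if np.isnan(v):
                    continue
                if not np.isnan(last_val):
                    gap_weeks = min(max((days[i] - last_day) / 7.0, 1.0), gap_cap_weeks)
                    limit = per_week * gap_weeks
                    delta = v - last_val
                    rule = None
                    if var == "height_cm" and delta < 0:
                        rule = "negative_height"
                    elif abs(delta) > limit and not (var == "height_cm" and delta < 0):
                        rule = "weekly_delta"
                    if rule is not None:
                        report.add(rule, var, [(child_id, sub["visit_date"].iloc[i])])
                        vals[i] = np.nan
                        continue  # anchor stays at the previous surviving value
                last_val, last_day = v, days[i]
            out.loc[idx, var] = vals
    return out, report


def clean_visits(
    visits: pd.DataFrame,
    reference: LMSTable,
    fence_k: float = 1.5,
    gap_cap_weeks: float = 4.0,
    restricted: bool = True,
):
    """Full cleaning pass: drop empty visits, bounds, longitudinal
    consistency, z-score computation, pooled z-outlier blanking.

    Returns the cleaned frame (with z-score columns) and a
    :class:`CleaningReport`.
    """
    visits = visits.sort_values(["child_id", "visit_date"], kind="stable").reset_index(drop=True)
    out, n_empty = drop_empty_visits(visits)
    report = CleaningReport(n_empty_visits_dropped=n_empty)
    out, report = flag_implausible_values(out, report)
    out, report = enforce_longitudinal_consistency(out, report, gap_cap_weeks)
    out = add_zscores(out, reference, restricted=restricted)
    for col in ZSCORE_COLUMNS:
        vals = out[col].to_numpy(dtype=float)
        if np.isfinite(vals).sum() >= 4:
            mask = flag_zscore_outliers(vals, fence_k)
            report.fences[col] = tukey_fences(vals, fence_k)
            if mask.any():
                report.add(
                    "z_outlier", col,
                    list(zip(out.loc[mask, "child_id"], out.loc[mask, "visit_date"])),
                )
                out.loc[mask, col] = np.nan
        # invariant: z missing whenever any input measurement is missing
        out.loc[out[ZSCORE_INPUT[col]].isna().any(axis=1), col] = np.nan
    out = out.reset_index(drop=True)
    return out, report
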