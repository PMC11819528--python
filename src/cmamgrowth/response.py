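"""Admission-to-exit gains and the quartile split of non-responders.

Non-responders are split at the first quartile (Q1) of their pooled
admission-to-exit gain: children who gained less than Q1 are
``low_growth_nr`` (the true treatment failures), children who gained at
least Q1 (ties included) are ``high_growth_nr`` (delayed responders).
Recovered children are never re-assigned.  Q1 uses linear interpolation
between order statistics (position 0.25*(n-1)); the convention is
configurable because the original study's printed thresholds depend on
its own pooled data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anthropometry import weight_gain_rate

SPLIT_INDICATORS = ("muac", "weight", "rate", "waz", "whz")

#: gain column per split indicator
GAIN_COLUMN = {
    "muac": "delta_muac", "weight": "delta_weight", "rate": "rate",
    "waz": "delta_waz", "whz": "delta_whz",
}

#: Headline values printed by the pooled 14-study analysis.  They depend on
#: the original (non-public) pooled data and are documented reference points
#: only — nothing in this package recomputes them from other inputs.
STUDY_REFERENCE_VALUES = {
    "non_responder_fraction_pct": 9.6,
    "q1_muac_gain_mm": 2.0,
    "q1_weight_gain_kg": 0.4,
    "q1_weight_gain_rate_g_kg_day": 0.6,
    "q1_waz_gain": 0.5,
    "q1_whz_gain": 0.0,
    "multivariate_model_accuracy_pct": 87.7,
    "multivariate_model_auc_pct": 74.1,
}

_DELTA_VARS = {
    "delta_muac": "muac_mm", "delta_weight": "weight_kg", "delta_height": "height_cm",
    "delta_whz": "whz", "delta_waz": "waz", "delta_haz": "haz", "delta_muacz": "muacz",
}


@dataclass
class QuantileThresholds:
    indicator: str
    q1: float
    n_used: int


def compute_gains(child_visits: pd.DataFrame) -> dict:
    """Admission-to-exit deltas, velocity and length of stay for one child.

    Admission values come from the first visit; exit values are the last
    non-missing observation per indicator.  A delta is missing whenever
    either endpoint is missing.  The g/kg/day velocity uses admission
    weight and the calendar days to the last non-missing weight.
    """
    dates = pd.to_datetime(child_visits["visit_date"])
    if not dates.is_monotonic_increasing:
        raise ValueError("visits must be sorted by date")
    out = {"child_id": child_visits["child_id"].iloc[0]}
    days = (dates - dates.iloc[0]).dt.days.to_numpy()
    for delta_name, var in _DELTA_VARS.items():
        vals = child_visits[var].to_numpy(dtype=float)
        adm = vals[0]
        non_missing = np.flatnonzero(np.isfinite(vals))
        exit_val = vals[non_missing[-1]] if non_missing.size else np.nan
        out[delta_name] = exit_val - adm if np.isfinite(adm) and np.isfinite(exit_val) else np.nan
        if var == "weight_kg":
            if (
                np.isfinite(adm) and non_missing.size
                and days[non_missing[-1]] > 0 and np.isfinite(exit_val)
            ):
                out["rate"] = weight_gain_rate(adm, exit_val, days[non_missing[-1]])
            else:
                out["rate"] = np.nan
    out["los_weeks"] = int(days[-1] // 7)
    return out


def compute_gains_frame(visits: pd.DataFrame) -> pd.DataFrame:
    """One :func:`compute_gains` row per child."""
    return pd.DataFrame(
        [compute_gains(sub) for _, sub in visits.groupby("child_id", sort=False)]
    )


def first_month_no_gain(child_visits: pd.DataFrame, var: str):
    """True when the child shows no gain (<= 0) in ``var`` over the first
    month: admission to the visit closest to day 28 within days 21-42.
    Missing (None) when no visit falls in the window or a value is
    missing.
    """
    dates = pd.to_datetime(child_visits["visit_date"])
    days = (dates - dates.iloc[0]).dt.days.to_numpy()
    in_window = np.flatnonzero((days >= 21) & (days <= 42))
    if in_window.size == 0:
        return None
    target = in_window[np.argmin(np.abs(days[in_window] - 28))]
    adm = child_visits[var].iloc[0]
    month = child_visits[var].iloc[target]
    if pd.isna(adm) or pd.isna(month):
        return None
    return bool(month - adm <= 0)


def q1_threshold(gains, indicator: str, q: float = 0.25,
                 method: str = "linear") -> QuantileThresholds:
    """First-quartile gain threshold over the non-responder pool."""
    if indicator not in SPLIT_INDICATORS:
        raise ValueError(f"unknown split indicator {indicator!r}")
    v = np.asarray(gains, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("need at least 4 non-missing non-responder gains")
    return QuantileThresholds(indicator, float(np.quantile(v, q, method=method)), int(v.size))


def assign_response_category(gain, q1: float, final_label):
    """Three-way response category per child.

    recovered -> ``recovered``; non-responders with gain >= q1 (ties
    high) -> ``high_growth_nr``; gain < q1 -> ``low_growth_nr``;
    missing gain -> ``unassigned``.
    """
    gain = np.asarray(gain, dtype=float)
    label = np.asarray(final_label, dtype=object)
    gain, label = np.broadcast_arrays(gain, label)
    bad = set(label.ravel()) - {"recovered", "non_responder"}
    if bad:
        raise ValueError(f"unexpected final labels: {sorted(map(str, bad))}")
    out = np.full(label.shape, "unassigned", dtype=object)
    out[label == "recovered"] = "recovered"
    nr = label == "non_responder"
    with np.errstate(invalid="ignore"):
        out[nr & (gain >= q1)] = "high_growth_nr"
        out[nr & (gain < q1)] = "low_growth_nr"
    return out if out.shape else out.item()


def split_non_responders(
    gains: pd.DataFrame,
    outcomes: pd.DataFrame,
    indicator: str = "muac",
    q: float = 0.25,
    method: str = "linear",
):
    """Join gains with final labels and split non-responders at Q1.

    Returns (categories frame with ``response_category`` column,
    QuantileThresholds).  The default indicator is MUAC gain, the
    threshold the study carried forward.
    """
    col = GAIN_COLUMN[indicator]
    merged = outcomes.merge(gains, on="child_id", how="left", validate="one_to_one")
    nr_gains = merged.loc[merged["final_label"] == "non_responder", col]
    thr = q1_threshold(nr_gains, indicator, q=q, method=method)
    merged["response_category"] = assign_response_category(
        merged[col].to_numpy(dtype=float), thr.q1, merged["final_label"].to_numpy(object)
    )
    return merged, thr
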