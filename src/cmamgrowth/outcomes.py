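"""Exit-outcome (re-)classification and analysis-set construction.

Study-assigned ``recovered`` and ``non_responder`` labels pass through
unchanged.  Children with oedema at admission, and children who died
or were transferred out for medical reasons, are excluded.  Children
whose studies labelled them ``defaulter`` or ``unknown`` are
re-classified from their exit anthropometry:

* recovered — at least one recovery criterion met at exit
  (MUAC >= 125 mm or WHZ >= -2), no oedema at the exit visit, and no
  remaining criterion of severe wasting (MUAC >= 115 mm and
  WHZ >= -3), with a length of stay of at least 12 weeks;
* non-responder — both MUAC < 125 mm and WHZ < -2 at exit, with at
  least 12 weeks of follow-up;
* otherwise excluded — short stay (< 12 weeks) or unclassifiable
  (missing exit anthropometry, or one recovery criterion met while the
  other indicator is still severely low: the two re-classification
  rules do not partition such cases, so they are left out rather than
  forced into either group).

Exit anthropometry is the last non-missing value per indicator, taken
separately for MUAC and WHZ (they may come from different final visits
when one is missing).  Length of stay is floor(days between first and
last visit / 7) weeks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ORIGINAL_LABELS = (
    "recovered", "non_responder", "defaulter", "unknown", "died", "medical_transfer",
)
RECLASSIFIABLE = ("defaulter", "unknown")

#: recovery / severity cut-offs (mm and z-units) and minimum stay (weeks)
MUAC_RECOVERY = 125.0
WHZ_RECOVERY = -2.0
MUAC_SEVERE = 115.0
WHZ_SEVERE = -3.0
DEFAULT_MIN_LOS_WEEKS = 12


@dataclass
class ExitOutcome:
    child_id: object
    original_label: str
    final_label: str            # recovered | non_responder | excluded
    exclusion_reason: str | None
    los_weeks: int
    reclassified: bool
    exit_muac_mm: float = np.nan
    exit_whz: float = np.nan

    def __post_init__(self):
        if (self.final_label == "excluded") != (self.exclusion_reason is not None):
            raise ValueError("excluded iff exclusion_reason set")
        if self.reclassified and self.original_label not in RECLASSIFIABLE:
            raise ValueError("only defaulter/unknown outcomes can be reclassified")


@dataclass
class FlowCounts:
    """Child counts mirroring the analysis flow chart."""

    n_input: int
    n_oedema_excluded: int
    n_other_excluded: int
    n_analysis: int
    n_recovered: int
    n_non_responder: int

    def __post_init__(self):
        if self.n_input != self.n_oedema_excluded + self.n_other_excluded + self.n_analysis:
            raise ValueError("flow counts do not conserve children")
        if self.n_analysis != self.n_recovered + self.n_non_responder:
            raise ValueError("analysis set must split into recovered + non-responder")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("children_in_pooled_data", self.n_input),
                ("excluded_oedema_at_admission", self.n_oedema_excluded),
                ("excluded_other", self.n_other_excluded),
                ("included_in_analysis", self.n_analysis),
                ("recovered", self.n_recovered),
                ("non_responder", self.n_non_responder),
            ],
            columns=["box", "n_children"],
        )


def _last_non_missing(series: pd.Series):
    vals = series.dropna()
    return (np.nan, None) if vals.empty else (float(vals.iloc[-1]), vals.index[-1])


def classify_exit(
    child_visits: pd.DataFrame,
    original_label: str,
    min_los_weeks: int = DEFAULT_MIN_LOS_WEEKS,
) -> ExitOutcome:
    """Classify one child's exit outcome from its cleaned visit series."""
    if original_label not in ORIGINAL_LABELS:
        raise ValueError(f"unknown study-assigned outcome: {original_label!r}")
    child_id = child_visits["child_id"].iloc[0]
    dates = pd.to_datetime(child_visits["visit_date"])
    if not dates.is_monotonic_increasing:
        raise ValueError(f"visits for child {child_id!r} are not sorted by date")
    los_weeks = int((dates.iloc[-1] - dates.iloc[0]).days // 7)

    def make(final, reason=None, reclassified=False, muac=np.nan, whz=np.nan):
        return ExitOutcome(child_id, original_label, final, reason, los_weeks,
                           reclassified, muac, whz)

    if bool(child_visits["oedema"].iloc[0]):
        return make("excluded", "oedema_at_admission")
    if original_label == "died":
        return make("excluded", "died")
    if original_label == "medical_transfer":
        return make("excluded", "medical_transfer")
    if original_label in ("recovered", "non_responder"):
        return make(original_label)

    # defaulter / unknown: re-classify from exit anthropometry
    if los_weeks < min_los_weeks:
        return make("excluded", "short_stay_lt_12wk")
    muac, muac_idx = _last_non_missing(child_visits["muac_mm"])
    whz, whz_idx = _last_non_missing(child_visits["whz"])
    if muac_idx is None and whz_idx is None:
        logger.warning("child %r has no usable exit anthropometry", child_id)
        return make("excluded", "unclassifiable")
    if muac_idx is not None and whz_idx is not None and muac_idx != whz_idx:
        logger.info("child %r: exit MUAC and WHZ taken from different visits", child_id)
    exit_visit_oedema = bool(child_visits["oedema"].iloc[-1])
    # NaN comparisons are False, so a missing indicator fails every criterion
    # it participates in and the child falls through to unclassifiable.
    recovered = (
        ((muac >= MUAC_RECOVERY) or (whz >= WHZ_RECOVERY))
        and not exit_visit_oedema
        and (muac >= MUAC_SEVERE)
        and (whz >= WHZ_SEVERE)
    )
    if recovered:
        return make("recovered", reclassified=True, muac=muac, whz=whz)
    if (muac < MUAC_RECOVERY) and (whz < WHZ_RECOVERY):
        return make("non_responder", reclassified=True, muac=muac, whz=whz)
    return make("excluded", "unclassifiable")


def classify_all(
    visits: pd.DataFrame,
    labels: pd.DataFrame,
    min_los_weeks: int = DEFAULT_MIN_LOS_WEEKS,
) -> pd.DataFrame:
    """Classify every child; ``labels`` has columns child_id, original_label."""
    label_map = labels.set_index("child_id")["original_label"]
    rows = []
    for child_id, sub in visits.groupby("child_id", sort=False):
        if child_id not in label_map.index:
            raise KeyError(f"no study-assigned outcome for child {child_id!r}")
        rows.append(vars(classify_exit(sub, label_map.loc[child_id], min_los_weeks)))
    return pd.DataFrame(rows)


def build_analysis_set(outcomes: pd.DataFrame):
    """Filter classified children to the analysis set and tally the flow.

    Parameters
    ----------
    outcomes : DataFrame
        One row per child as produced by :func:`classify_all`.

    Returns
    -------
    (analysis, FlowCounts) where ``analysis`` contains only children
    with final_label recovered or non_responder.
    """
    if outcomes["child_id"].duplicated().any():
        raise ValueError("duplicate children in classified outcomes")
    analysis = outcomes[outcomes["final_label"].isin(["recovered", "non_responder"])].copy()
    n_oed = int((outcomes["exclusion_reason"] == "oedema_at_admission").sum())
    excluded = outcomes["final_label"] == "excluded"
    flow = FlowCounts(
        n_input=len(outcomes),
        n_oedema_excluded=n_oed,
        n_other_excluded=int(excluded.sum()) - n_oed,
        n_analysis=len(analysis),
        n_recovered=int((analysis["final_label"] == "recovered").sum()),
        n_non_responder=int((analysis["final_label"] == "non_responder").sum()),
    )
    return analysis, flow
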