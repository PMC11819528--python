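"""Synthetic longitudinal CMAM cohorts with planted latent growth classes.

Each simulated child belongs to one of three latent classes:

* ``recovering`` — saturating MUAC and WHZ trajectories that plateau
  near the recovery thresholds (MUAC 125 mm / WHZ -2);
* ``delayed_responder`` — the same curve family shifted down at
  admission (anchored to the pooled-study medians: admission MUAC
  around 111 mm vs 120 mm for recovering children), growing steadily
  but usually still below the thresholds at the maximum stay;
* ``non_grower`` — flat MUAC and weight with continuing height growth.

Weight is derived from the planted WHZ trajectory by inverting the LMS
reference at the child's current height (for non-growers, weight is
planted flat and WHZ follows), so z-scores recomputed by the pipeline
recover the planted trajectories up to measurement noise.  Children
exit when their *observed* anthropometry crosses a recovery threshold
(study label ``recovered``) or at the maximum stay (``non_responder``);
weekly geometric dropout produces ``defaulter`` records, and small
fractions die, transfer out, carry oedema at admission, or get an
``unknown`` label, so every exclusion and re-classification branch of
the pipeline is exercised.  Identical configs (including seed) produce
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .anthropometry import add_zscores
from .lms import DAYS_PER_MONTH, LMSTable, synthetic_lms_table

CLASSES = ("recovering", "delayed_responder", "non_grower")
_WEEK_MONTHS = 7.0 / DAYS_PER_MONTH


class ClassAnchors(BaseModel):
    """Per-class admission and growth anchors for one latent class."""

    muac0_mean: float
    muac0_sd: float = 4.0
    whz0_mean: float
    whz0_sd: float = 0.4
    age_median_months: float = 17.0
    muac_lift_mean: float = 0.0   # planted total MUAC rise to the asymptote (mm)
    muac_lift_sd: float = 0.0
    whz_lift_mean: float = 0.0
    whz_lift_sd: float = 0.0
    tau_weeks: float = 5.0        # saturation time constant
    morbidity_prob: float = 0.6


class SimConfig(BaseModel):
    """Full configuration of the cohort generator.

    Defaults emulate the pooled-study conditions: latent-class mix
    0.86 / 0.105 / 0.035 (non-growers are one quarter of the
    non-responder pool), admission MUAC medians 120 / 111 / 120 mm,
    57% girls, 20% oedema at admission, weekly visits for up to 16
    weeks, and field-realistic measurement noise (2 mm MUAC, 0.1 kg
    weight, 0.5 cm height).
    """

    n_children: int = Field(gt=0)
    seed: int  # mandatory: all randomness flows from here
    class_proportions: tuple[float, float, float] = (0.86, 0.105, 0.035)
    max_weeks: int = 16
    visit_interval_weeks: int = 1
    start_date: str = "2023-01-02"
    female_fraction: float = 0.57
    age_sd_log: float = 0.5
    haz0_mean: float = -2.7
    haz0_sd: float = 1.1
    haz_drift_per_week: float = 0.02
    noise_muac_mm: float = 2.0
    noise_weight_kg: float = 0.1
    noise_height_cm: float = 0.5
    nongrower_weight_gain_sd_kg: float = 0.08
    nongrower_muac_gain_sd_mm: float = 1.2
    dropout_hazard_per_week: float = 0.01
    consecutive_visits_for_discharge: int = 2
    p_oedema: float = 0.20
    p_died: float = 0.005
    p_transfer: float = 0.005
    p_unknown_label: float = 0.02
    morbidity_visit_prob: float = 0.35
    anchors: dict[str, ClassAnchors] = None

    @model_validator(mode="after")
    def _check(self):
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if min(self.class_proportions) < 0:
            raise ValueError("class proportions must be non-negative")
        for f in ("noise_muac_mm", "noise_weight_kg", "noise_height_cm",
                  "age_sd_log", "haz0_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.anchors is None:
            self.anchors = default_anchors()
        return self


def default_anchors() -> dict[str, ClassAnchors]:
    return {
        "recovering": ClassAnchors(
            muac0_mean=120.0, whz0_mean=-2.4, age_median_months=17.0,
            muac_lift_mean=12.0, muac_lift_sd=2.5,
            whz_lift_mean=1.2, whz_lift_sd=0.3, tau_weeks=5.0,
            morbidity_prob=0.59,
        ),
        "delayed_responder": ClassAnchors(
            muac0_mean=111.0, whz0_mean=-3.0, age_median_months=14.0,
            muac_lift_mean=11.0, muac_lift_sd=2.0,
            whz_lift_mean=0.7, whz_lift_sd=0.2, tau_weeks=7.0,
            morbidity_prob=0.61,
        ),
        "non_grower": ClassAnchors(
            muac0_mean=120.0, whz0_mean=-2.9, age_median_months=18.0,
            tau_weeks=7.0, morbidity_prob=0.77,
        ),
    }


@dataclass
class SyntheticCohort:
    """Observed visit records plus the planted (noise-free) truth."""

    visits: pd.DataFrame      # the standard visit schema + z-scores omitted
    labels: pd.DataFrame      # child_id, original_label
    truth: pd.DataFrame       # per child: latent class, planted exit values/gains
    config: SimConfig


def _saturating(t, start, lift, tau):
    return start + lift * (1.0 - np.exp(-t / tau))


def simulate_cohort(config: SimConfig, reference: LMSTable | None = None) -> SyntheticCohort:
    """Generate a cohort under ``config`` (deterministic given the seed)."""
    ref = reference if reference is not None else LMSTable(synthetic_lms_table())
    rng = np.random.default_rng(config.seed)
    start = pd.Timestamp(config.start_date)
    classes = rng.choice(len(CLASSES), size=config.n_children, p=config.class_proportions)
    rows, label_rows, truth_rows = [], [], []

    for i in range(config.n_children):
        cls = CLASSES[classes[i]]
        a = config.anchors[cls]
        child_id = f"C{i:05d}"
        sex = "female" if rng.random() < config.female_fraction else "male"
        age0 = float(np.clip(np.exp(rng.normal(np.log(a.age_median_months),
                                               config.age_sd_log)), 6.0, 59.0))
        muac0 = rng.normal(a.muac0_mean, a.muac0_sd)
        whz0 = rng.normal(a.whz0_mean, a.whz0_sd)
        haz0 = rng.normal(config.haz0_mean, config.haz0_sd)
        muac_lift = max(rng.normal(a.muac_lift_mean, a.muac_lift_sd), 0.0)
        whz_lift = max(rng.normal(a.whz_lift_mean, a.whz_lift_sd), 0.0)
        oedema = rng.random() < config.p_oedema
        fate = rng.random()
        died = fate < config.p_died
        transfer = config.p_died <= fate < config.p_died + config.p_transfer
        event_week = rng.integers(1, config.max_weeks) if (died or transfer) else None
        dropout_week = None
        if config.dropout_hazard_per_week > 0:
            g = rng.geometric(config.dropout_hazard_per_week)
            if g <= config.max_weeks:
                dropout_week = int(g)

        weeks = np.arange(0, config.max_weeks + 1, config.visit_interval_weeks)
        t = weeks.astype(float)
        age_m = age0 + t * _WEEK_MONTHS
        age_days = age_m * DAYS_PER_MONTH
        haz_t = haz0 + config.haz_drift_per_week * t
        height_t = ref.inverse("HAZ", [sex] * len(t), age_days, haz_t)
        if cls == "non_grower":
            # plant weight flat; WHZ follows from the growing height
            whz_at_adm = whz0
            w0 = float(np.ravel(ref.inverse("WHZ", sex, height_t[0] * 10.0, whz_at_adm))[0])
            w_gain = rng.normal(0.0, config.nongrower_weight_gain_sd_kg)
            weight_t = w0 + w_gain * t / max(t[-1], 1.0)
            muac_gain = rng.normal(0.0, config.nongrower_muac_gain_sd_mm)
            muac_t = muac0 + muac_gain * t / max(t[-1], 1.0)
        else:
            whz_t = _saturating(t, whz0, whz_lift, a.tau_weeks)
            weight_t = ref.inverse("WHZ", [sex] * len(t), height_t * 10.0, whz_t)
            muac_t = _saturating(t, muac0, muac_lift, a.tau_weeks)

        # observed measurements
        obs_muac = muac_t + rng.normal(0.0, config.noise_muac_mm, len(t))
        obs_weight = weight_t + rng.normal(0.0, config.noise_weight_kg, len(t))
        obs_height = height_t + rng.normal(0.0, config.noise_height_cm, len(t))
        L, M, S = ref.lookup("WHZ", np.array([sex] * len(t), dtype=object),
                             obs_height * 10.0)
        with np.errstate(invalid="ignore"):
            obs_whz = (np.power(obs_weight / M, L) - 1.0) / (L * S)

        # exit: discharge once the observed anthropometry meets a recovery
        # threshold for the required consecutive visits; else the maximum stay
        need = config.consecutive_visits_for_discharge
        with np.errstate(invalid="ignore"):
            meets = (obs_muac >= 125.0) | (obs_whz >= -2.0)
        recovered_at = None
        streak = 0
        for j in range(1, len(weeks)):
            streak = streak + 1 if meets[j] else 0
            if streak >= need:
                recovered_at = j
                break
        if died or transfer:
            last = min(event_week, weeks[-1])
            label = "died" if died else "medical_transfer"
        elif dropout_week is not None and (
            recovered_at is None or dropout_week < weeks[recovered_at]
        ):
            last = dropout_week
            label = "defaulter"
        elif recovered_at is not None:
            last = weeks[recovered_at]
            label = "recovered"
        else:
            last = weeks[-1]
            label = "non_responder"
        if label in ("recovered", "non_responder") and rng.random() < config.p_unknown_label:
            label = "unknown"

        keep = weeks <= last
        any_morbidity = rng.random() < a.morbidity_prob
        morb = (
            rng.random(len(t)) < config.morbidity_visit_prob
            if any_morbidity else np.zeros(len(t), dtype=bool)
        )
        if any_morbidity and not morb[keep].any():
            morb[0] = True
        for j in np.flatnonzero(keep):
            rows.append(
                (
                    child_id, "S01", start + pd.Timedelta(days=int(weeks[j] * 7)),
                    round(age_m[j], 3), sex,
                    round(obs_weight[j], 3), round(obs_height[j], 2),
                    round(obs_muac[j], 1), bool(oedema and j == 0), bool(morb[j]),
                )
            )
        label_rows.append((child_id, label))
        j_last = int(np.flatnonzero(keep)[-1])
        truth_rows.append(
            {
                "child_id": child_id,
                "latent_class": cls,
                "true_muac_adm": muac_t[0],
                "true_muac_exit": muac_t[j_last],
                "true_muac_gain": muac_t[j_last] - muac_t[0],
                "true_weight_adm": weight_t[0],
                "true_weight_exit": weight_t[j_last],
                "true_weight_gain": weight_t[j_last] - weight_t[0],
                "true_height_gain": height_t[j_last] - height_t[0],
                "los_weeks": int(weeks[j_last]),
                "oedema": bool(oedema),
                "original_label": label,
            }
        )

    visits = pd.DataFrame(
        rows,
        columns=[
            "child_id", "study_id", "visit_date", "age_months", "sex",
            "weight_kg", "height_cm", "muac_mm", "oedema", "morbidity",
        ],
    )
    labels = pd.DataFrame(label_rows, columns=["child_id", "original_label"])
    return SyntheticCohort(visits=visits, labels=labels,
                           truth=pd.DataFrame(truth_rows), config=config)


def truth_labels(cohort: SyntheticCohort) -> pd.DataFrame:
    """Planted latent class and noise-free exit values per child."""
    return cohort.truth.copy()


def expected_category(latent_class: str) -> str:
    """Pipeline response category the planted class is meant to land in."""
    return {
        "recovering": "recovered",
        "delayed_responder": "high_growth_nr",
        "non_grower": "low_growth_nr",
    }[latent_class]
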