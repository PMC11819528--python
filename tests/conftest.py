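import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cmamgrowth.lms import LMSTable, synthetic_lms_table

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from cmamgrowth.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def reference() -> LMSTable:
    return LMSTable(synthetic_lms_table())


@pytest.fixture(scope="session")
def small_cohort():
    """300-child cohort under default (study-anchored) conditions."""
    return simulate_cohort(SimConfig(n_children=300, seed=20240601))


@pytest.fixture(scope="session")
def low_noise_cohort():
    """2,000 children with halved measurement noise, for recovery checks."""
    cfg = SimConfig(
        n_children=2000, seed=11,
        noise_muac_mm=1.0, noise_weight_kg=0.05, noise_height_cm=0.25,
    )
    return simulate_cohort(cfg)


def make_visits(child_id, values, start="2023-01-02", sex="male", age0=24.0,
                weeks=None, study_id="S01"):
    """Hand-build a visit frame from a dict of measurement lists."""
    n = len(next(iter(values.values())))
    weeks = list(range(n)) if weeks is None else weeks
    start = pd.Timestamp(start)
    return pd.DataFrame(
        {
            "child_id": child_id,
            "study_id": study_id,
            "visit_date": [start + pd.Timedelta(days=7 * w) for w in weeks],
            "age_months": [age0 + w * 7 / 30.4375 for w in weeks],
            "sex": sex,
            "weight_kg": values.get("weight_kg", [np.nan] * n),
            "height_cm": values.get("height_cm", [np.nan] * n),
            "muac_mm": values.get("muac_mm", [np.nan] * n),
            "oedema": values.get("oedema", [False] * n),
            "morbidity": values.get("morbidity", [False] * n),
        }
    )
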