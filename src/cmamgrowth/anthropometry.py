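"""Z-scores, wasting-severity classification and velocities.

Visit-level data are pandas DataFrames with one row per measurement
occasion and columns::

    child_id, study_id, visit_date, age_months, sex,
    weight_kg, height_cm, muac_mm, oedema, morbidity

Derived z-score columns (``whz, waz, haz, muacz``) are added by
:func:`add_zscores`.  A z-score is missing exactly when its input
measurement (or its reference lookup) is missing — values are never
imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lms import DAYS_PER_MONTH, LMSTable

#: indicators that get the WHO-style restricted adjustment for |z| > 3
RESTRICTED_INDICATORS = ("WHZ", "WAZ")

VISIT_COLUMNS = [
    "child_id", "study_id", "visit_date", "age_months", "sex",
    "weight_kg", "height_cm", "muac_mm", "oedema", "morbidity",
]
ZSCORE_COLUMNS = ["whz", "waz", "haz", "muacz"]
#: measurements feeding each z-score
ZSCORE_INPUT = {"whz": ["weight_kg", "height_cm"], "waz": ["weight_kg"],
                "haz": ["height_cm"], "muacz": ["muac_mm"]}


def lms_zscore(x, L, M, S):
    """Box-Cox (LMS) z-score of measurement ``x``.

    z = ((x/M)**L - 1) / (L*S) for L != 0, else log(x/M)/S.  NaNs
    propagate; non-positive finite ``x``, ``M`` or ``S`` raise
    ``ValueError``.
    """
    x, L, M, S = (np.asarray(v, dtype=float) for v in (x, L, M, S))
    for name, v in (("x", x), ("M", M), ("S", S)):
        if np.any(v[np.isfinite(v)] <= 0):
            raise ValueError(f"{name} must be positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = x / M
        z = np.where(
            np.isclose(L, 0.0),
            np.log(ratio) / S,
            (np.power(ratio, L) - 1.0) / (np.where(np.isclose(L, 0.0), 1.0, L) * S),
        )
    return z if z.shape else float(z)


def _sd_bound(L, M, S, z):
    return M * np.power(1.0 + L * S * z, 1.0 / L)


def restricted_lms_zscore(x, L, M, S):
    """LMS z-score with the WHO restricted adjustment beyond +/-3 SD.

    For |z| > 3 the score is recomputed on a linear scale anchored at
    the +/-3 SD bounds: z = 3 + (x - sd3)/(sd3 - sd2) above, and
    symmetrically below.  This caps the influence of the Box-Cox tail
    on extreme weight-based measurements.
    """
    x, L, M, S = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (x, L, M, S))
    )
    z = np.asarray(lms_zscore(x, L, M, S))
    with np.errstate(invalid="ignore"):
        hi = z > 3
        lo = z < -3
        if np.any(hi):
            sd3 = _sd_bound(L, M, S, 3.0)
            sd2 = _sd_bound(L, M, S, 2.0)
            z = np.where(hi, 3.0 + (x - sd3) / (sd3 - sd2), z)
        if np.any(lo):
            sd3n = _sd_bound(L, M, S, -3.0)
            sd2n = _sd_bound(L, M, S, -2.0)
            z = np.where(lo, -3.0 + (x - sd3n) / (sd2n - sd3n), z)
    return z if z.shape else float(z)


def add_zscores(visits: pd.DataFrame, reference: LMSTable,
                restricted: bool = True) -> pd.DataFrame:
    """Attach whz/waz/haz/muacz columns to a visit frame.

    WAZ/HAZ/MUACZ are keyed by age in days (``age_months`` *
    30.4375); WHZ by the same visit's height in mm.  With
    ``restricted=True`` (default) the WHO restricted adjustment is
    applied to the weight-based indicators (WHZ, WAZ).
    """
    out = visits.copy()
    age_days = out["age_months"].to_numpy(dtype=float) * DAYS_PER_MONTH
    sex = out["sex"].to_numpy(dtype=object)
    keys = {
        "waz": age_days, "haz": age_days, "muacz": age_days,
        "whz": out["height_cm"].to_numpy(dtype=float) * 10.0,
    }
    values = {
        "waz": out["weight_kg"], "haz": out["height_cm"],
        "muacz": out["muac_mm"], "whz": out["weight_kg"],
    }
    for col in ZSCORE_COLUMNS:
        ind = col.upper()
        L, M, S = reference.lookup(ind, sex, keys[col])
        x = values[col].to_numpy(dtype=float)
        if restricted and ind in RESTRICTED_INDICATORS:
            z = restricted_lms_zscore(x, L, M, S)
        else:
            z = lms_zscore(x, L, M, S)
        out[col] = z
    return out


def classify_severity(muac_mm, whz, oedema=False):
    """Wasting severity from MUAC (mm) and WHZ, oedema excluded upstream.

    severe: MUAC < 115 mm or WHZ < -3; moderate: 115 <= MUAC < 125 mm
    or -3 <= WHZ < -2 (and not severe); otherwise not wasted.  Both
    inputs missing -> NaN (unclassifiable).  Vectorized.
    """
    muac = np.asarray(muac_mm, dtype=float)
    whz = np.asarray(whz, dtype=float)
    oed = np.asarray(oedema, dtype=bool)
    if np.any(oed):
        raise ValueError("oedema cases must be excluded before severity classification")
    muac, whz = np.broadcast_arrays(muac, whz)
    scalar = muac.shape == ()
    muac, whz = np.atleast_1d(muac), np.atleast_1d(whz)
    out = np.full(muac.shape, None, dtype=object)
    both_missing = np.isnan(muac) & np.isnan(whz)
    with np.errstate(invalid="ignore"):
        severe = (muac < 115) | (whz < -3)
        moderate = ~severe & (((muac >= 115) & (muac < 125)) | ((whz >= -3) & (whz < -2)))
    out[severe] = "severe_wasting"
    out[moderate] = "moderate_wasting"
    out[~severe & ~moderate & ~both_missing] = "not_wasted"
    out[both_missing] = np.nan
    return out.item() if scalar else out


def derive_flags(whz, haz, waz):
    """(wast, severe_underweight): concurrent wasting-and-stunting is
    WHZ < -2 and HAZ < -2; severe underweight is WAZ < -3.  Missing
    inputs yield missing flags (pandas nullable booleans).
    """
    whz = pd.Series(np.atleast_1d(np.asarray(whz, dtype=float)))
    haz = pd.Series(np.atleast_1d(np.asarray(haz, dtype=float)))
    waz = pd.Series(np.atleast_1d(np.asarray(waz, dtype=float)))
    wast = ((whz < -2) & (haz < -2)).astype("boolean")
    wast[whz.isna() | haz.isna()] = pd.NA
    severe_uw = (waz < -3).astype("boolean")
    severe_uw[waz.isna()] = pd.NA
    return wast, severe_uw


def weight_gain_rate(w_adm, w_exit, duration_days):
    """Weight gain velocity in g/kg/day over admission weight.

    rate = 1000 * (w_exit - w_adm) / (w_adm * duration_days).
    """
    w_adm = np.asarray(w_adm, dtype=float)
    w_exit = np.asarray(w_exit, dtype=float)
    duration = np.asarray(duration_days, dtype=float)
    if np.any(w_adm[np.isfinite(w_adm)] <= 0):
        raise ValueError("admission weight must be positive")
    if np.any(duration[np.isfinite(duration)] <= 0):
        raise ValueError("duration must be positive")
    rate = 1000.0 * (w_exit - w_adm) / (w_adm * duration)
    return rate if rate.shape else float(rate)
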