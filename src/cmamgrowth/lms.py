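"""LMS growth-reference tables and lookups.

Anthropometric z-scores are computed with the LMS method: a reference
table gives, for each indicator, sex and key (age in days, or
length/height in mm for weight-for-height), the Box-Cox power ``L``,
the median ``M`` and the coefficient of variation ``S`` of the healthy
reference distribution.  The z-score of a measurement ``x`` is then

    z = ((x / M)**L - 1) / (L * S)     if L != 0
    z = log(x / M) / S                 if L == 0

Tables are delimited text with columns ``indicator,sex,key,L,M,S``.
The package bundles a *synthetic* reference (see
:func:`synthetic_lms_table`): a smooth, internally consistent set of
curves with realistic child-growth magnitudes, generated by code and
clearly labelled synthetic.  Analyses of real programme data should load
the WHO 2006 standards in the same format via :func:`load_lms_table`.
"""

from __future__ import annotations

import importlib.resources
import logging
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INDICATORS = ("WHZ", "WAZ", "HAZ", "MUACZ")
SEXES = ("male", "female")

#: days per month used when converting ages to reference keys
DAYS_PER_MONTH = 30.4375

_REQUIRED_COLUMNS = ["indicator", "sex", "key", "L", "M", "S"]


class LMSTable:
    """A validated LMS reference with interpolating lookups.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``indicator, sex, key, L, M, S``.  Keys are age in days
        for WAZ/HAZ/MUACZ and length/height in mm for WHZ, strictly
        increasing within each (indicator, sex) block.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"LMS table missing columns: {missing}")
        frame = frame[_REQUIRED_COLUMNS].copy()
        bad_sex = set(frame["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex values in LMS table: {sorted(bad_sex)}")
        bad_ind = set(frame["indicator"]) - set(INDICATORS)
        if bad_ind:
            raise ValueError(f"unknown indicators in LMS table: {sorted(bad_ind)}")
        if (frame["M"] <= 0).any() or (frame["S"] <= 0).any():
            raise ValueError("LMS table requires M > 0 and S > 0")
        self._curves: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        for (ind, sex), block in frame.groupby(["indicator", "sex"], sort=False):
            block = block.sort_values("key")
            keys = block["key"].to_numpy(dtype=float)
            if np.any(np.diff(keys) <= 0):
                raise ValueError(f"keys not strictly increasing for ({ind}, {sex})")
            self._curves[(ind, sex)] = {
                "key": keys,
                "L": block["L"].to_numpy(dtype=float),
                "M": block["M"].to_numpy(dtype=float),
                "S": block["S"].to_numpy(dtype=float),
            }
        self.frame = frame.sort_values(["indicator", "sex", "key"]).reset_index(drop=True)
        self.n_out_of_range = 0

    def lookup(self, indicator: str, sex, key) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolate (L, M, S) at ``key`` for vectors of sex/key.

        Linear interpolation between tabulated keys; keys outside the
        tabulated range yield NaN (counted in ``n_out_of_range`` and
        logged), never an extrapolated value.
        """
        sex = np.asarray(sex, dtype=object)
        key = np.asarray(key, dtype=float)
        if sex.shape == ():
            sex = sex.reshape(1)
            key = key.reshape(1)
        bad = set(sex[pd.notna(sex)]) - set(SEXES)
        if bad:
            raise ValueError(f"unknown sex values: {sorted(bad)}")
        L = np.full(key.shape, np.nan)
        M = np.full(key.shape, np.nan)
        S = np.full(key.shape, np.nan)
        for s in SEXES:
            curve = self._curves.get((indicator, s))
            if curve is None:
                continue
            sel = (sex == s) & np.isfinite(key)
            if not sel.any():
                continue
            k = key[sel]
            in_range = (k >= curve["key"][0]) & (k <= curve["key"][-1])
            n_out = int((~in_range).sum())
            if n_out:
                self.n_out_of_range += n_out
                logger.warning(
                    "%d %s lookup key(s) outside reference range for %s; set missing",
                    n_out, indicator, s,
                )
            vals_L = np.interp(k, curve["key"], curve["L"])
            vals_M = np.interp(k, curve["key"], curve["M"])
            vals_S = np.interp(k, curve["key"], curve["S"])
            vals_L[~in_range] = np.nan
            vals_M[~in_range] = np.nan
            vals_S[~in_range] = np.nan
            L[sel], M[sel], S[sel] = vals_L, vals_M, vals_S
        return L, M, S

    def inverse(self, indicator: str, sex, key, z):
        """Measurement value at z-score ``z``: x = M * (1 + L*S*z)**(1/L)."""
        L, M, S = self.lookup(indicator, sex, key)
        z = np.asarray(z, dtype=float)
        with np.errstate(invalid="ignore"):
            x = np.where(
                np.isclose(L, 0.0),
                M * np.exp(S * z),
                M * np.power(1.0 + L * S * z, 1.0 / np.where(np.isclose(L, 0.0), 1.0, L)),
            )
        return x


def load_lms_table(path) -> LMSTable:
    """Read a delimited LMS reference file (``indicator,sex,key,L,M,S``)."""
    return LMSTable(pd.read_csv(path))


def synthetic_lms_table() -> pd.DataFrame:
    """Generate the bundled synthetic LMS reference as a DataFrame.

    The curves are smooth parametric stand-ins with realistic magnitudes
    for children aged 0-66 months (weight-for-age, height-for-age,
    MUAC-for-age keyed by age in days; weight-for-height keyed by
    length/height 450-1200 mm).  They are NOT the WHO 2006 standards and
    must not be used to score real children; they exist so that every
    pipeline stage is exercisable end to end on simulated cohorts.
    """
    rows = []
    months = np.arange(0, 67)
    days = np.round(months * DAYS_PER_MONTH).astype(int)
    for sex in SEXES:
        f = sex == "female"
        # height-for-age: fast infant growth saturating into a linear phase
        m_h = 50.0 + 28.0 * (1.0 - np.exp(-months / 9.0)) + 0.55 * months - (1.0 if f else 0.0)
        for d, m in zip(days, m_h):
            rows.append(("HAZ", sex, d, 1.0, round(m, 3), 0.035))
        # weight-for-age
        m_w = (3.3 + 6.0 * (1.0 - np.exp(-months / 7.5)) + 0.16 * months) * (0.93 if f else 1.0)
        for d, m in zip(days, m_w):
            rows.append(("WAZ", sex, d, -0.2, round(m, 3), 0.12))
        # MUAC-for-age (mm)
        m_mu = 125.0 + 22.0 * (1.0 - np.exp(-months / 6.0)) + 0.32 * months - (2.0 if f else 0.0)
        for d, m in zip(days, m_mu):
            rows.append(("MUACZ", sex, d, -0.2, round(m, 3), 0.085))
        # weight-for-height, quadratic in height (cm), keyed in mm
        heights_mm = np.arange(450, 1205, 5)
        h_cm = heights_mm / 10.0
        m_wh = (0.914 + 0.011667 * h_cm + 0.0013556 * h_cm**2) * (0.97 if f else 1.0)
        for k, m in zip(heights_mm, m_wh):
            rows.append(("WHZ", sex, int(k), -0.35, round(m, 3), 0.082))
    return pd.DataFrame(rows, columns=_REQUIRED_COLUMNS)


def bundled_synthetic_reference() -> LMSTable:
    """Load the packaged synthetic LMS reference file."""
    with importlib.resources.files("cmamgrowth.data").joinpath(
        "synthetic_lms.csv"
    ).open("r") as fh:
        return LMSTable(pd.read_csv(fh))
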