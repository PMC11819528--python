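"""Published outcome-by-covariate counts from the pooled 14-study dataset.

The pooled analysis reported, for 15,958 analysed children
(13,727 recovered, 1,513 high-growth non-responders, 718 low-growth
non-responders under the MUAC-gain split), per-level counts for its
admission covariates.  Those printed counts fully determine the
univariate multinomial odds ratios for categorical predictors, so they
serve as an exact verification surface for this package's contingency
closed form and iterative multinomial fit.  Counts for the binary
"complete-case" covariates are reconstructed by subtracting the
printed "yes" and "unknown" rows from the group totals.
"""

from __future__ import annotations

import pandas as pd

from .multinomial import ContingencyTable

GROUP_TOTALS = {"recovered": 13_727, "high_growth_nr": 1_513, "low_growth_nr": 718}

_OUTCOMES = ["recovered", "high_growth_nr", "low_growth_nr"]


def _table(levels_counts: dict, baseline: str) -> ContingencyTable:
    df = pd.DataFrame.from_dict(levels_counts, orient="index", columns=_OUTCOMES)
    return ContingencyTable(df, baseline)


def pooled_count_tables() -> dict[str, ContingencyTable]:
    """Outcome-by-level count tables for each published categorical
    covariate (counts recovered / high-growth NR / low-growth NR)."""
    totals = [GROUP_TOTALS[o] for o in _OUTCOMES]

    def complement(yes, unknown=(0, 0, 0)):
        return [t - y - u for t, y, u in zip(totals, yes, unknown)]

    return {
        "sex": _table(
            {"female": [7_756, 906, 387], "male": [5_971, 607, 331]}, "female"
        ),
        "age_category": _table(
            {
                "6-11": [3_956, 601, 213],
                "12-23": [5_111, 456, 219],
                "24-59": [4_660, 456, 286],
            },
            "6-11",
        ),
        "acute_malnutrition": _table(
            {"SAM": [5_546, 1_181, 357], "MAM": [8_181, 332, 361]}, "SAM"
        ),
        "whz_category": _table(
            {">=-3": [9_609, 665, 395], "<-3": [3_046, 678, 275]}, ">=-3"
        ),
        "wasted_and_stunted": _table(
            {
                "yes": [6_182, 711, 363],
                "no": complement([6_182, 711, 363], unknown=[1_089, 173, 49]),
            },
            "no",
        ),
        "no_weight_gain_first_month": _table(
            {"yes": [3_665, 639, 384], "no": complement([3_665, 639, 384])}, "no"
        ),
        "no_muac_gain_first_month": _table(
            {"yes": [3_540, 601, 396], "no": complement([3_540, 601, 396])}, "no"
        ),
        "morbidity": _table(
            {
                "yes": [6_889, 719, 394],
                "no": complement([6_889, 719, 394], unknown=[2_055, 342, 203]),
            },
            "no",
        ),
    }


#: the published univariate odds ratios these tables reproduce, keyed by
#: (covariate, level, outcome contrast) — used in verification tests
PUBLISHED_UNIVARIATE_OR = {
    ("sex", "male", "high_growth_nr"): 0.87,
    ("sex", "male", "low_growth_nr"): 1.11,
    ("age_category", "12-23", "high_growth_nr"): 0.59,
    ("age_category", "24-59", "high_growth_nr"): 0.64,
    ("acute_malnutrition", "MAM", "high_growth_nr"): 0.19,
    ("acute_malnutrition", "MAM", "low_growth_nr"): 0.69,
    ("whz_category", "<-3", "high_growth_nr"): 3.22,
    ("whz_category", "<-3", "low_growth_nr"): 2.20,
    ("wasted_and_stunted", "yes", "high_growth_nr"): 1.18,
    ("no_weight_gain_first_month", "yes", "high_growth_nr"): 2.01,
    ("no_weight_gain_first_month", "yes", "low_growth_nr"): 3.16,
    ("no_muac_gain_first_month", "yes", "high_growth_nr"): 1.90,
    ("no_muac_gain_first_month", "yes", "low_growth_nr"): 3.54,
    ("morbidity", "yes", "low_growth_nr"): 2.26,
}
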