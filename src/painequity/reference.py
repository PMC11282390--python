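"""Published descriptive margins of the CHARLS 2011 pain cohort.

These are the wave-1 (2011) baseline counts for the 16,747 adults aged >=45
years analysed in the CHARLS pain-inequality literature.  They parameterise
the synthetic cohort generator (marginal category frequencies, severity and
site mixes) and serve as fixed arithmetic inputs for consistency checks.
All counts are raw integers; probabilities are derived by normalisation so
no rounding error is baked in.
"""

from __future__ import annotations

REFERENCE_N = 16_747

AGE_MEAN = 59.57
AGE_SD = 9.82

#: overall-column counts by covariate, in display order
CATEGORY_COUNTS: dict[str, dict[str, int]] = {
    "gender": {"male": 8196, "female": 8551},
    "education": {
        "illiterate": 4631,
        "primary": 6574,
        "secondary": 5146,
        "university": 396,
    },
    "marital": {"never_married": 156, "married": 14_567, "sep_div_wid": 2024},
    "smoking": {"nonsmoker": 11_377, "smoker": 5370},
    "drinking": {"never": 9779, "occasionally": 1705, "regularly": 5263},
    "bmi_class": {"under25": 12_701, "bmi25_30": 3372, "over30": 674},
    "location": {"rural": 12_888, "urban": 3859},
}

N_PAIN = 5449
N_DEATHS = 394

#: severity counts among pain cases with a recorded severity (denominator 5426)
SEVERITY_COUNTS = {"mild": 1358, "moderate": 1973, "severe": 2095}
N_SEVERITY_DENOM = 5426  # 23 of the 5449 pain cases lack a severity grade

#: the 15 pain sites in questionnaire order, counts over the full cohort
SITE_COUNTS = {
    "head": 2250,
    "shoulders": 2038,
    "arms": 1655,
    "wrists": 1057,
    "fingers": 990,
    "chest": 1068,
    "stomach": 1436,
    "back": 1533,
    "waist": 3232,
    "buttocks": 633,
    "legs": 2476,
    "knees": 2178,
    "ankles": 960,
    "toes": 563,
    "neck": 1135,
}

SITES = tuple(SITE_COUNTS)

#: published decomposition of the pain concentration index (elasticity,
#: category concentration index) by variable and category, reference
#: categories omitted.  Used for internal-consistency arithmetic only.
DECOMPOSITION_ROWS: list[tuple[str, str, float, float]] = [
    ("age_group", "60-75", 0.077, -0.075),
    ("age_group", ">=75", -0.018, -0.123),
    ("gender", "female", 0.890, -0.004),
    ("education", "illiterate", 0.803, -0.204),
    ("education", "primary", 1.105, -0.055),
    ("education", "secondary", 0.439, 0.202),
    ("marital", "never_married", 0.001, -0.178),
    ("marital", "sep_div_wid", 0.037, -0.036),
    ("smoking", "smoker", 0.031, -0.016),
    ("drinking", "never", -0.256, -0.008),
    ("drinking", "occasionally", -0.026, 0.019),
    ("bmi_class", "under25", 0.026, -0.014),
    ("bmi_class", "bmi25_30", 0.045, 0.037),
    ("econ", "tertile1", 0.141, -0.667),
    ("econ", "tertile2", 0.162, 0.000),
    ("location", "rural", 1.073, -0.129),
]

#: published per-variable contribution rates (%), same variable keys
PUBLISHED_RATES = {
    "age_group": 0.94,
    "gender": 0.90,
    "education": 36.49,
    "marital": 0.38,
    "smoking": 0.14,
    "drinking": -0.42,
    "bmi_class": -0.35,
    "econ": 25.05,
    "location": 36.87,
}


def category_probs() -> dict[str, dict[str, float]]:
    """Marginal category probabilities derived from the reference counts."""
    out = {}
    for var, counts in CATEGORY_COUNTS.items():
        total = sum(counts.values())
        out[var] = {k: v / total for k, v in counts.items()}
    return out
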