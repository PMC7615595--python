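"""Column schema and canonical feature order for cohort tables.

A cohort is a :class:`pandas.DataFrame` with one row per participant.  Raw
measurement columns are on natural scales (cm, kg, mmHg, mmol/L, %, mg/dL);
derived risk-factor columns are appended by :mod:`cardiorenal.derived`.
"""

from __future__ import annotations

# Ordered 10-feature clustering vector (natural measurement scales):
# height cm, BMI kg/m^2, waist-to-height ratio, SBP mmHg, DBP mmHg,
# resting heart rate bpm, HDL mmol/L, non-HDL mmol/L, HbA1c %, eGFR ml/min/1.73m^2
FEATURES = [
    "height",
    "bmi",
    "whtr",
    "sbp",
    "dbp",
    "rhr",
    "hdl",
    "non_hdl",
    "hba1c",
    "egfr",
]

#: risk runs downward for these features (taller, higher HDL, higher eGFR = lower risk)
REVERSED_FEATURES = {"height", "hdl", "egfr"}

N_BP_READINGS = 3
SBP_READING_COLS = [f"sbp_{i}" for i in range(1, N_BP_READINGS + 1)]
DBP_READING_COLS = [f"dbp_{i}" for i in range(1, N_BP_READINGS + 1)]

ID_COL = "id"
SEXES = ("female", "male")

#: raw measurement columns required to derive the full feature vector
RAW_NUMERIC_COLS = (
    ["height", "body_weight", "waist"]
    + SBP_READING_COLS
    + DBP_READING_COLS
    + ["rhr", "tc", "hdl", "hba1c", "scr"]
)

CATEGORICAL_LEVELS = {
    "ethnicity": ["non_hispanic_white", "non_hispanic_black", "hispanic", "other"],
    "education": ["below_high_school", "high_school", "university_or_college"],
    "smoking": ["never", "former", "current"],
}

BINARY_FLAGS = [
    "med_antihypertensive",
    "med_statin",
    "med_oral_hypoglycemic",
    "med_insulin",
    "hist_mi",
    "hist_stroke",
    "hist_chf",
]

MANDATORY_COLS = (
    [ID_COL, "sex", "age", "round", "mid_year", "weight_sample"]
    + RAW_NUMERIC_COLS
    + list(CATEGORICAL_LEVELS)
    + BINARY_FLAGS
)

#: 5-year age bands 20-24 ... 80-84, 85+
AGE_BAND_EDGES = list(range(20, 90, 5))  # lower edges; last band is open-ended


def age_band_labels() -> list[str]:
    labels = [f"{lo}-{lo + 4}" for lo in AGE_BAND_EDGES[:-1]]
    labels.append(f"{AGE_BAND_EDGES[-1]}+")
    return labels


def assign_age_band(age):
    """Vectorized 5-year age-band label for ages >= 20."""
    import numpy as np
    import pandas as pd

    age = np.asarray(age)
    idx = np.clip((age - 20) // 5, 0, len(AGE_BAND_EDGES) - 1).astype(int)
    labels = np.array(age_band_labels())
    out = labels[idx]
    return pd.Categorical(out, categories=age_band_labels())
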