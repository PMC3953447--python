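"""Published summary statistics of the German EPIC MRI validation sub-study.

The sub-study measured whole-body MRI compartment volumes and anthropometry in
1,192 cohort members (598 men, 594 women) sampled from two centers with equal
representation of three 10-year baseline age bands.  What survives in print —
and what this module transcribes — are:

* per sex × age-band marginals, ``mean (min, max)``, for the anthropometric
  variables and the six MRI compartment volumes;
* the sex-specific 9×9 Pearson correlation matrices of the age/height-adjusted
  variables (BMI, WC, HC, TBV, TAT, SAT, VAT, CAT, SMT).

These published values serve two roles: worked-example ground truth for the
correlation/regression machinery, and calibration targets for the synthetic
cohort generator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: canonical variable order of the published correlation matrices
CORR_LABELS = ["BMI", "WC", "HC", "TBV", "TAT", "SAT", "VAT", "CAT", "SMT"]

#: anthropometric predictors used in every multiple-regression model
PREDICTORS = ["BMI", "WC", "HC"]

#: MRI compartment outcomes modeled per sex
OUTCOMES = ["TBV", "TAT", "SAT", "VAT", "CAT", "SMT"]

#: cohort-column name for each correlation-matrix label
COLUMN_FOR_LABEL = {
    "BMI": "bmi", "WC": "waist_cm", "HC": "hip_cm",
    "TBV": "tbv_l", "TAT": "tat_l", "SAT": "sat_l",
    "VAT": "vat_l", "CAT": "cat_l", "SMT": "smt_l",
}

N_MEN = 598
N_WOMEN = 594
N_BY_SEX = {"male": N_MEN, "female": N_WOMEN}

#: baseline 10-year age bands of the sampling design (inclusive integer ages)
BASELINE_AGE_BANDS = [(35, 44), (45, 54), (55, 64)]

#: per-band participant counts actually realized (men, then women)
BAND_COUNTS = {"male": [191, 194, 213], "female": [207, 196, 191]}

# ---------------------------------------------------------------------------
# Sex × age-band marginals: {sex: {variable: [(mean, min, max)] * 3 bands}}
# Variables keyed by cohort-CSV column name; volumes in liters.
# ---------------------------------------------------------------------------
MARGINALS = {
    "male": {
        "weight_kg": [(85.9, 53.4, 128.5), (85.5, 55.6, 125.9), (80.8, 56.9, 113.5)],
        "height_cm": [(177.6, 160.0, 197.5), (175.5, 156.9, 198.6), (173.2, 155.2, 191.1)],
        "bmi":       [(27.2, 18.6, 40.8), (27.7, 20.2, 38.3), (26.9, 19.1, 38.9)],
        "waist_cm":  [(99.2, 73.3, 130.3), (102.1, 82.9, 139.7), (101.1, 74.3, 130.6)],
        "hip_cm":    [(101.8, 85.5, 123.0), (102.2, 78.3, 122.0), (101.1, 86.9, 127.1)],
        "tbv_l":     [(73.3, 48.2, 110.0), (73.8, 48.4, 109.4), (70.1, 50.4, 98.5)],
        "tat_l":     [(20.7, 4.9, 45.5), (22.1, 6.6, 41.0), (20.9, 5.2, 42.5)],
        "vat_l":     [(4.8, 0.48, 11.5), (5.4, 1.39, 10.5), (5.5, 0.24, 10.5)],
        "sat_l":     [(15.5, 3.9, 36.6), (16.1, 5.1, 34.3), (14.9, 4.9, 34.9)],
        "cat_l":     [(0.42, 0.07, 0.96), (0.50, 0.10, 1.1), (0.51, 0.10, 1.5)],
        "smt_l":     [(25.4, 16.6, 35.4), (24.3, 17.9, 33.1), (22.6, 16.4, 29.5)],
    },
    "female": {
        "weight_kg": [(71.0, 44.4, 116.2), (70.3, 43.9, 116.7), (68.6, 42.1, 107.0)],
        "height_cm": [(164.8, 152.0, 183.1), (162.5, 142.5, 180.2), (161.3, 147.1, 179.0)],
        "bmi":       [(26.2, 17.1, 40.8), (26.6, 18.0, 42.1), (26.3, 17.1, 40.5)],
        "waist_cm":  [(88.9, 63.6, 126.0), (91.3, 66.2, 128.3), (90.9, 63.6, 119.0)],
        "hip_cm":    [(103.3, 80.0, 137.7), (104.2, 84.8, 141.2), (103.3, 83.6, 129.6)],
        "tbv_l":     [(63.4, 38.2, 104.1), (63.4, 37.5, 110.6), (61.8, 37.1, 95.3)],
        "tat_l":     [(24.3, 6.4, 50.9), (25.1, 9.4, 62.7), (24.0, 8.3, 44.1)],
        "vat_l":     [(2.7, 0.30, 7.3), (3.0, 0.47, 7.5), (3.2, 0.63, 7.9)],
        "sat_l":     [(21.4, 5.9, 43.6), (21.7, 8.2, 56.4), (20.5, 7.2, 36.9)],
        "cat_l":     [(0.24, 0.01, 0.60), (0.31, 0.04, 1.2), (0.32, 0.04, 1.3)],
        "smt_l":     [(16.9, 11.4, 23.3), (16.2, 11.2, 22.4), (15.8, 10.7, 20.7)],
    },
}

# ---------------------------------------------------------------------------
# Published age/height-adjusted Pearson correlation matrices (lower triangles
# as printed; 2 decimal places).
# ---------------------------------------------------------------------------
_MEN_LOWER = {
    ("WC", "BMI"): 0.91,
    ("HC", "BMI"): 0.86, ("HC", "WC"): 0.82,
    ("TBV", "BMI"): 0.96, ("TBV", "WC"): 0.92, ("TBV", "HC"): 0.87,
    ("TAT", "BMI"): 0.89, ("TAT", "WC"): 0.91, ("TAT", "HC"): 0.84,
    ("TAT", "TBV"): 0.92,
    ("SAT", "BMI"): 0.87, ("SAT", "WC"): 0.87, ("SAT", "HC"): 0.85,
    ("SAT", "TBV"): 0.90, ("SAT", "TAT"): 0.97,
    ("VAT", "BMI"): 0.75, ("VAT", "WC"): 0.80, ("VAT", "HC"): 0.64,
    ("VAT", "TBV"): 0.78, ("VAT", "TAT"): 0.85, ("VAT", "SAT"): 0.70,
    ("CAT", "BMI"): 0.65, ("CAT", "WC"): 0.70, ("CAT", "HC"): 0.55,
    ("CAT", "TBV"): 0.67, ("CAT", "TAT"): 0.75, ("CAT", "SAT"): 0.65,
    ("CAT", "VAT"): 0.80,
    ("SMT", "BMI"): 0.63, ("SMT", "WC"): 0.49, ("SMT", "HC"): 0.46,
    ("SMT", "TBV"): 0.62, ("SMT", "TAT"): 0.33, ("SMT", "SAT"): 0.28,
    ("SMT", "VAT"): 0.38, ("SMT", "CAT"): 0.24,
}

_WOMEN_LOWER = {
    ("WC", "BMI"): 0.89,
    ("HC", "BMI"): 0.93, ("HC", "WC"): 0.85,
    ("TBV", "BMI"): 0.98, ("TBV", "WC"): 0.89, ("TBV", "HC"): 0.94,
    ("TAT", "BMI"): 0.95, ("TAT", "WC"): 0.88, ("TAT", "HC"): 0.94,
    ("TAT", "TBV"): 0.97,
    ("SAT", "BMI"): 0.94, ("SAT", "WC"): 0.85, ("SAT", "HC"): 0.94,
    ("SAT", "TBV"): 0.96, ("SAT", "TAT"): 0.99,
    ("VAT", "BMI"): 0.77, ("VAT", "WC"): 0.80, ("VAT", "HC"): 0.70,
    ("VAT", "TBV"): 0.78, ("VAT", "TAT"): 0.80, ("VAT", "SAT"): 0.71,
    ("CAT", "BMI"): 0.61, ("CAT", "WC"): 0.65, ("CAT", "HC"): 0.56,
    ("CAT", "TBV"): 0.62, ("CAT", "TAT"): 0.64, ("CAT", "SAT"): 0.57,
    ("CAT", "VAT"): 0.75,
    ("SMT", "BMI"): 0.69, ("SMT", "WC"): 0.63, ("SMT", "HC"): 0.56,
    ("SMT", "TBV"): 0.68, ("SMT", "TAT"): 0.53, ("SMT", "SAT"): 0.50,
    ("SMT", "VAT"): 0.50, ("SMT", "CAT"): 0.39,
}


def _to_frame(lower: dict) -> pd.DataFrame:
    m = np.eye(len(CORR_LABELS))
    for (a, b), r in lower.items():
        i, j = CORR_LABELS.index(a), CORR_LABELS.index(b)
        m[i, j] = m[j, i] = r
    return pd.DataFrame(m, index=CORR_LABELS, columns=CORR_LABELS)


def adjusted_corr_target(sex: str) -> pd.DataFrame:
    """Published age/height-adjusted correlation matrix for one sex.

    Returns a fresh labeled 9×9 DataFrame (unit diagonal, symmetric).
    """
    if sex == "male":
        return _to_frame(_MEN_LOWER)
    if sex == "female":
        return _to_frame(_WOMEN_LOWER)
    raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


def band_mean(sex: str, variable: str) -> np.ndarray:
    """Per-band published means of one variable, length 3."""
    return np.array([m for m, _, _ in MARGINALS[sex][variable]])
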