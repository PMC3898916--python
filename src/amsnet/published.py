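"""Published summary tables from the source study.

These printed values are *inputs* for reproduction of in-table arithmetic
(per-symptom mean coefficients, Fisher-z intervals, column percentages,
chi-squared balance test); the underlying record-level dataset is not
publicly archived.
"""

from __future__ import annotations

import pandas as pd

from .records import SYMPTOMS

#: Number of subjects behind the pairwise correlation table (one
#: questionnaire per subject: longitudinal arm day 3 plus the whole
#: cross-sectional arm).
TABLE1_N = 269

#: Pairwise Spearman coefficients between the five symptom composites.
TABLE1_RHO: dict[tuple[str, str], float] = {
    ("sleep", "gi_upset"): 0.23,
    ("sleep", "dizziness"): 0.20,
    ("sleep", "headache"): 0.25,
    ("sleep", "fatigue"): 0.30,
    ("gi_upset", "dizziness"): 0.58,
    ("gi_upset", "headache"): 0.43,
    ("gi_upset", "fatigue"): 0.44,
    ("dizziness", "headache"): 0.57,
    ("dizziness", "fatigue"): 0.40,
    ("headache", "fatigue"): 0.38,
}

#: Printed 95% confidence bounds for each pair (2 dp).
TABLE1_CI: dict[tuple[str, str], tuple[float, float]] = {
    ("sleep", "gi_upset"): (0.11, 0.34),
    ("sleep", "dizziness"): (0.08, 0.32),
    ("sleep", "headache"): (0.13, 0.36),
    ("sleep", "fatigue"): (0.18, 0.41),
    ("gi_upset", "dizziness"): (0.49, 0.65),
    ("gi_upset", "headache"): (0.33, 0.53),
    ("gi_upset", "fatigue"): (0.33, 0.53),
    ("dizziness", "headache"): (0.48, 0.65),
    ("dizziness", "fatigue"): (0.29, 0.50),
    ("headache", "fatigue"): (0.27, 0.48),
}

#: Printed per-symptom means of the four off-diagonal coefficients.
TABLE1_MEAN_ROW: dict[str, float] = {
    "sleep": 0.25,
    "gi_upset": 0.42,
    "dizziness": 0.44,
    "headache": 0.41,
    "fatigue": 0.38,
}


def table1_rho_frame() -> pd.DataFrame:
    """The printed pairwise coefficients as a symmetric 5x5 DataFrame."""
    rho = pd.DataFrame(1.0, index=list(SYMPTOMS), columns=list(SYMPTOMS))
    for (a, b), r in TABLE1_RHO.items():
        rho.loc[a, b] = rho.loc[b, a] = r
    return rho


#: Treatment-arm counts within each symptom cluster (longitudinal arm only;
#: cluster totals exclude records with unknown treatment).
TABLE2_COUNTS = pd.DataFrame(
    {
        "cluster_1": [130, 157, 57],
        "cluster_2": [47, 38, 30],
        "cluster_3": [17, 17, 7],
    },
    index=["placebo", "antioxidant", "sildenafil"],
)

#: Printed column percentages (1 dp).
TABLE2_PERCENTAGES = pd.DataFrame(
    {
        "cluster_1": [37.8, 45.6, 16.6],
        "cluster_2": [40.9, 33.0, 26.1],
        "cluster_3": [41.5, 41.5, 17.1],
    },
    index=["placebo", "antioxidant", "sildenafil"],
)
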