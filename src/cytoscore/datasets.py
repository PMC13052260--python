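"""Built-in example clinical tables.

``discovery_cohort_metadata`` reconstructs the published discovery
cohort's patient-level clinical structure (32 pan-cancer patients on a
PD-1 inhibitor; 15 developed irAEs) from its printed onset / type /
grade counts: 6 of 15 irAEs were early-onset (0-90 days), among them 4
of the 7 pneumonias, 1 of the 4 cutaneous irAEs and a day-52
myocarditis; 3 of the 6 early-onset events were Grade >= 3. Onset days
other than the printed day-52 myocarditis are synthetic placeholders
consistent with the early/late classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["discovery_cohort_metadata"]

# (irae_type, grade, onset_day); grade 0 / NaN onset = no irAE
_IRAE_PATIENTS = [
    ("pneumonia", 4, 30),
    ("pneumonia", 3, 45),
    ("pneumonia", 2, 60),
    ("pneumonia", 2, 80),
    ("myocarditis", 4, 52),
    ("cutaneous", 1, 40),
    ("pneumonia", 3, 120),
    ("pneumonia", 3, 150),
    ("pneumonia", 2, 200),
    ("cutaneous", 2, 100),
    ("cutaneous", 2, 130),
    ("cutaneous", 3, 180),
    ("endocrine", 2, 100),
    ("enteritis", 3, 95),
    ("enteritis", 3, 110),
]


def discovery_cohort_metadata(n_total: int = 32) -> pd.DataFrame:
    """Patient-level clinical table mirroring the printed cohort counts.

    Returns a DataFrame with columns sample_id, group, irae_type, grade,
    onset_day; ``group`` is "irAE" or "non_irAE".
    """
    if n_total < len(_IRAE_PATIENTS):
        raise ValueError("cohort smaller than its irAE patient count")
    rows = []
    for i, (t, grade, onset) in enumerate(_IRAE_PATIENTS):
        rows.append(
            {
                "sample_id": f"P{i + 1:03d}",
                "group": "irAE",
                "irae_type": t,
                "grade": grade,
                "onset_day": float(onset),
            }
        )
    for i in range(len(_IRAE_PATIENTS), n_total):
        rows.append(
            {
                "sample_id": f"P{i + 1:03d}",
                "group": "non_irAE",
                "irae_type": None,
                "grade": 0,
                "onset_day": np.nan,
            }
        )
    return pd.DataFrame(rows)
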