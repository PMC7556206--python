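"""Packaged reference cohort: the published 16-patient dual-pathology study.

Two tables transcribed from the study report ship with the package:
clinical metadata (lesion pathologies, surgery, outcome, seizure-
generating group) and the per-patient fast-ripple asymmetry analysis
(ratio R, true group, rank-predicted group, correctness). They let the
prediction and permutation machinery be exercised on the real cohort
without access to the raw SEEG, which was never deposited.
"""
from __future__ import annotations

import pandas as pd

__all__ = ["load_fixture", "REFERENCE"]

#: Headline results reported for this cohort in the original study, used
#: by ``reproduce-study`` to print a side-by-side comparison: 11 of 16
#: correct rank-based assignments (69%), permutation p below 0.01, and
#: Spearman rho = -0.52 (p < 0.05) between group and fast-ripple ratio.
REFERENCE = {
    "n_correct": 11,
    "n_patients": 16,
    "accuracy_pct": 69.0,
    "spearman_rho": -0.52,
    "spearman_p_max": 0.05,
    "permutation_p_max": 0.01,
}

# (r_fr, patient_id, true_group, predicted_group, correct) in descending
# rank order of the fast-ripple ratio.
_TABLE2 = [
    (0.61, 2, 1, 1, True),
    (0.60, 12, 1, 1, True),
    (0.36, 13, 3, 1, False),
    (0.34, 1, 1, 1, True),
    (0.27, 10, 2, 1, False),
    (0.25, 3, 2, 2, True),
    (0.20, 5, 2, 2, True),
    (0.15, 15, 2, 2, True),
    (0.14, 4, 1, 2, False),
    (0.05, 8, 1, 2, False),
    (0.02, 7, 2, 2, True),
    (0.02, 16, 2, 2, True),
    (0.01, 9, 3, 3, True),
    (0.01, 14, 3, 3, True),
    (-0.05, 6, 2, 3, False),
    (-0.05, 11, 3, 3, True),
]

# (patient_id, hemisphere, hippocampal lesion, neocortical lesion,
#  surgery, 12-month Engel outcome, seizure-generating group)
_TABLE1 = [
    (1, "L", "HS", "FCD", None, None, 1),
    (2, "R", "HS", "FCD", "ATL", "IIB", 1),
    (3, "R", "HS", "Gliotic area/gray-white blurring", "ATL", "IA", 2),
    (4, "R", "HS", "FCD", "ATL", "IA", 1),
    (5, "L", "Hc malformation", "FCD", None, None, 2),
    (6, "L", "HS", "FCD", "EL + Hc resection", "IB", 2),
    (7, "R", "HS", "FCD", "ATL", "IIIA", 2),
    (8, "R", "HS", "FCD", "ATL", "IIA", 1),
    (9, "R", "HS", "FCD", "ATL", "IA", 3),
    (10, "R", "HS", "Gliotic area/gray-white blurring", "ATL", "IVB", 2),
    (11, "L", "Hc malformation", "Meningoencephalocele",
     "Temporal pole resection", "IA", 3),
    (12, "L", "HS", "Mild MCD", "ATL", "IA", 1),
    (13, "R", "Hc gliosis", "FCD", "ATL", "IA", 3),
    (14, "R", "Hc gliosis", "Meningoencephalocele",
     "Temporal pole resection + AH", "IA", 3),
    (15, "R", "HS", "Mild MCD", "ATL", "IA", 2),
    (16, "R", "Hc gliosis", "Mild MCD", "ATL", "IA", 2),
]


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged reference table.

    ``table2`` returns the per-patient fast-ripple analysis as a cohort
    table (patient_id, true_group, r_fr) plus the published
    predicted_group and correct columns for cross-checking; ``table1``
    returns clinical metadata with the group labels (counts 5/7/4).
    Surgical outcome is carried as metadata only.
    """
    if name == "table2":
        return pd.DataFrame(
            _TABLE2,
            columns=["r_fr", "patient_id", "true_group",
                     "predicted_group", "correct"],
        )[["patient_id", "true_group", "r_fr", "predicted_group", "correct"]]
    if name == "table1":
        return pd.DataFrame(
            _TABLE1,
            columns=["patient_id", "hemisphere", "hippocampal_lesion",
                     "neocortical_lesion", "surgery", "outcome_engel_12m",
                     "group"],
        )
    raise ValueError(f"unknown fixture {name!r}; expected 'table1' or 'table2'")
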