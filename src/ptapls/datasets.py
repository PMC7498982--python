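"""Bundled reference tables.

:func:`severe_tbi_patient_characteristics` returns the published
per-patient clinical characteristics of the 14-patient severe-TBI
rehabilitation cohort this pipeline was designed around: initial Glasgow
Coma Scale (GCS) score, Injury Severity Score (ISS), days of mechanical
ventilation, Glasgow Outcome Scale Extended (GOSE) one year after
injury, and duration of post-traumatic amnesia (PTA, days).  One patient
died 173 days post-injury; their GOSE and PTA are missing.

These values let the clinical-summary utilities be exercised against a
real cohort without any imaging data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["severe_tbi_patient_characteristics"]

_ROWS = [
    # id, mechanism, gcs, iss, ventilation_days, gose_1y, pta_days
    ("01", "traffic accident", 4, 24, 12, 6, 76),
    ("02", "fall", 3, 35, 33, 3, 221),
    ("03", "uncertain", 6, 25, 14, 4, 356),
    ("04", "traffic accident", 3, 30, 39, 3, 365),
    ("05", "traffic accident", 3, 59, 25, np.nan, np.nan),
    ("06", "traffic accident", 3, 27, 29, 7, 77),
    ("07", "fall", 3, 16, 20, 3, 199),
    ("08", "fall", 8, 31, 29, 4, 62),
    ("09", "traffic accident", 4, 33, 20, 4, 104),
    ("10", "traffic accident", 3, 34, 16, 4, 330),
    ("11", "traffic accident", 6, 27, 27, 4, 286),
    ("12", "traffic accident", 3, 43, 15, 6, 102),
    ("13", "traffic accident", 7, 24, 13, 3, 86),
    ("14", "traffic accident", 3, 43, 18, 6, 212),
]


def severe_tbi_patient_characteristics() -> pd.DataFrame:
    """Per-patient clinical characteristics of the reference cohort.

    Returns a DataFrame indexed by patient id with columns
    ``mechanism, gcs, iss, ventilation_days, gose_1y, pta_days``.
    """
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "patient",
            "mechanism",
            "gcs",
            "iss",
            "ventilation_days",
            "gose_1y",
            "pta_days",
        ],
    )
    return df.set_index("patient")
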