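"""Published 18-infant validation cohort for the screening rule.

Index values (mm and percent) for eight regular heads (H1–H8) and ten heads
treated for deformational plagiocephaly (P1–P10), as printed in the clinical
study the screening thresholds come from. The table is used to validate the
flagging logic: with the strict 4 mm rule and the inclusive 94–106 % OCLR
band, exactly the printed out-of-range values are flagged and exactly one
head (P10, initially judged regular on visual assessment) is reclassified
to DP.

Columns: cranial perimeter CP (mm), cephalic index CI (%), cranial vault
asymmetry AI/CVAI (mm), anterior and posterior asymmetry AAI/PAI (mm),
oblique cranial length ratio OCLR (%), plus the initial (pre-screening)
and final labels.
"""

from __future__ import annotations

import pandas as pd

_COLUMNS = ("id", "CP", "CI", "AI", "AAI", "PAI", "OCLR", "initial", "final")

_ROWS = [
    ("H1", 435, 85, -2, -2, 0, 101, "Healthy", "Healthy"),
    ("H2", 487, 84, 1, 2, -1, 99, "Healthy", "Healthy"),
    ("H3", 480, 81, 2, 0, 2, 99, "Healthy", "Healthy"),
    ("H4", 423, 81, -2, 2, -4, 101, "Healthy", "Healthy"),
    ("H5", 453, 78, -3, 1, -3, 102, "Healthy", "Healthy"),
    ("H6", 493, 78, 4, 1, 1, 98, "Healthy", "Healthy"),
    ("H7", 424, 81, -2, 0, -2, 101, "Healthy", "Healthy"),
    ("H8", 404, 85, 3, 2, 2, 98, "Healthy", "Healthy"),
    ("P1", 401, 84, -4, -5, 1, 103, "DP", "DP"),
    ("P2", 410, 84, -12, -2, -10, 108, "DP", "DP"),
    ("P3", 376, 89, -9, -3, -6, 106, "DP", "DP"),
    ("P4", 415, 90, -10, -3, -8, 105, "DP", "DP"),
    ("P5", 405, 89, 5, 9, -4, 97, "DP", "DP"),
    ("P6", 478, 87, -13, -4, -9, 108, "DP", "DP"),
    ("P7", 503, 76, 9, 1, 8, 94, "DP", "DP"),
    ("P8", 439, 87, -8, -4, -4, 104, "DP", "DP"),
    ("P9", 372, 79, 4, 9, -4, 98, "DP", "DP"),
    ("P10", 460, 86, 12, 5, 7, 93, "Healthy", "DP"),
]

#: Magnitudes printed as out-of-range (italicized) per head, for rule validation.
FLAGGED_VALUES: dict[str, set[str]] = {
    "H1": set(), "H2": set(), "H3": set(), "H4": set(),
    "H5": set(), "H6": set(), "H7": set(), "H8": set(),
    "P1": {"AAI"},
    "P2": {"AI", "PAI", "OCLR"},
    "P3": {"AI", "PAI"},
    "P4": {"AI", "PAI"},
    "P5": {"AI", "AAI"},
    "P6": {"AI", "PAI", "OCLR"},
    "P7": {"AI", "PAI"},
    "P8": {"AI"},
    "P9": {"AAI"},
    "P10": {"AI", "AAI", "PAI", "OCLR"},
}


def load_reference_cohort() -> pd.DataFrame:
    """The printed per-head index table as a DataFrame (one row per head)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
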