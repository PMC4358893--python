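"""Published reference values for healthy brain at 3 T.

The per-subject gray-matter values of the nine-adult reference cohort on
which the two-pool Z-spectrum technique was established, plus the group
summaries for white matter.  These serve as default phantom presets, as a
worked example for the statistics layer, and as regression anchors in tests.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "healthy_gm_table",
    "WM_SUMMARY",
    "GM_SUMMARY",
]

# Per-subject GM rows of the healthy reference cohort:
# (subject, sex, age, F_f, T2_f us, F_r, T2_r us)
_GM_ROWS = [
    (1, "M", 33, 0.83, 804.0, 0.17, 11.7),
    (2, "M", 35, 0.82, 815.0, 0.18, 18.4),
    (3, "F", 36, 0.84, 698.0, 0.16, 23.5),
    (4, "F", 38, 0.79, 789.0, 0.21, 13.5),
    (5, "M", 48, 0.83, 763.0, 0.17, 14.1),
    (6, "M", 51, 0.86, 804.0, 0.14, 19.1),
    (7, "M", 55, 0.83, 699.0, 0.17, 21.5),
    (8, "M", 59, 0.85, 809.0, 0.15, 15.0),
    (9, "M", 71, 0.82, 880.0, 0.18, 22.3),
]

# Group mean +/- SD for each tissue (per-subject WM values were not
# published; WM is available only at the summary level).
GM_SUMMARY = {
    "f_free": (0.83, 0.02),
    "t2_free_us": (785.0, 58.0),
    "f_restricted": (0.17, 0.02),
    "t2_restricted_us": (17.7, 4.3),
}
WM_SUMMARY = {
    "f_free": (0.72, 0.03),
    "t2_free_us": (671.0, 41.0),
    "f_restricted": (0.28, 0.03),
    "t2_restricted_us": (23.4, 3.7),
}


def healthy_gm_table() -> pd.DataFrame:
    """The nine healthy subjects' gray-matter rows as a cohort table."""
    return pd.DataFrame(
        [
            {
                "subject_id": f"sub-{i:03d}",
                "age": float(age),
                "sex": sex,
                "tissue": "GM",
                "f_free": ff,
                "f_restricted": fr,
                "t2_free_us": t2f,
                "t2_restricted_us": t2r,
            }
            for i, sex, age, ff, t2f, fr, t2r in _GM_ROWS
        ]
    )
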