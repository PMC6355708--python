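"""Small built-in reference datasets.

Currently: the published per-day mixed-model contrast table from a 21-day
head-down-tilt bed-rest study of seven male subjects (urinary delta44/42 vs
the lumped BDC baseline), useful as a worked example for delay detection.
"""

from __future__ import annotations

import pandas as pd

from .timecourse import ContrastResult

__all__ = ["reference_contrast_table", "reference_contrast_frame"]

# BDC row: baseline level (printed P "<0.001", stored as 0.0005).
# Other rows: change vs BDC (permil), 1SE, a-priori contrast P.
_TABLE = (
    ("BDC", 0.45, 0.12, 0.0005),
    ("HDT02", 0.08, 0.05, 0.1407),
    ("HDT10", -0.01, 0.06, 0.9034),
    ("HDT21", -0.15, 0.05, 0.0037),
    ("R+0", -0.11, 0.05, 0.0344),
    ("R+02", -0.11, 0.05, 0.0307),
    ("R+05", -0.17, 0.05, 0.0011),
    ("R+14", 0.03, 0.05, 0.5769),
    ("R+28", 0.06, 0.05, 0.2551),
)


def reference_contrast_table() -> list[ContrastResult]:
    """The published bed-rest contrast table as ContrastResult rows."""
    return [ContrastResult(*row) for row in _TABLE]


def reference_contrast_frame() -> pd.DataFrame:
    """The same table as a DataFrame (day_label, blup_permil, se_permil, p_value)."""
    return pd.DataFrame(
        _TABLE, columns=["day_label", "blup_permil", "se_permil", "p_value"]
    )
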