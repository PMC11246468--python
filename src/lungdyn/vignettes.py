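"""Gestational-week vignette bins.

Development is stratified into early / mid / late windows. Two presets are
shipped because the source conventions differ by one week at the late
boundary: trajectory work uses late = GW17-19, ligand-receptor work uses
late = GW18-19 (GW17 then falls in no vignette and is dropped).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TRAJECTORY_VIGNETTES: dict[str, tuple[int, int]] = {
    "early": (10, 13), "mid": (14, 16), "late": (17, 19)}
SIGNALING_VIGNETTES: dict[str, tuple[int, int]] = {
    "early": (10, 13), "mid": (14, 16), "late": (18, 19)}

VIGNETTE_ORDER = ("early", "mid", "late")


def assign_vignette(gestational_week, bounds: dict[str, tuple[int, int]]
                    ) -> pd.Series:
    """Map integer gestational weeks to vignette labels (NaN if unbinned)."""
    gw = pd.Series(gestational_week)
    out = pd.Series(pd.NA, index=gw.index, dtype="object")
    for name, (lo, hi) in bounds.items():
        out[(gw >= lo) & (gw <= hi)] = name
    return out
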