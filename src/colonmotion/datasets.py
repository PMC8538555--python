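"""Small bundled reference data.

``reference_cov_cell_means`` returns the published cell-mean CoV scores
(%) from tagged MRI scans of the dynamic colon model under the full
2 x 2 x 2 condition grid: CPPW speed (slower 0.4 cm/s vs faster),
media viscosity (LOVIS 0.25 % NaCMC, 13 mPa s vs HIVIS 0.50 %, 98 mPa s)
and media volume (150 vs 200 mL); n = 4 scans per cell, replicate-level
values not published.  These cell means are the inputs for the standalone
Tukey mean-difference contrasts.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_cov_cell_means"]

_CELL_MEANS = [
    # (pattern, viscosity, volume_ml, cov_percent)
    ("slower", "LOVIS", 150, 32.16),
    ("slower", "LOVIS", 200, 30.23),
    ("slower", "HIVIS", 150, 26.52),
    ("slower", "HIVIS", 200, 25.68),
    ("faster", "LOVIS", 150, 37.29),
    ("faster", "LOVIS", 200, 37.42),
    ("faster", "HIVIS", 150, 32.35),
    ("faster", "HIVIS", 200, 31.98),
]


def reference_cov_cell_means() -> pd.DataFrame:
    """The eight published CoV cell means (%) as a tidy table.

    Columns: pattern, viscosity, volume_ml, replicate (all 1: these are
    cell means, not replicates), cov_percent.
    """
    rows = [
        {"pattern": p, "viscosity": v, "volume_ml": vol, "replicate": 1,
         "cov_percent": cov}
        for p, v, vol, cov in _CELL_MEANS
    ]
    return pd.DataFrame(rows)
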