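"""Turn condition mean scores into standardized equity weights.

Shows the full chain on a small hand-sized panel: tertile categorization,
MCH reassignment to the high-category minimum, and min-max standardization
to [1, 2].
"""

import numpy as np
import pandas as pd

from equicea.equity import build_equity_table
from equicea.panel_io import ScoreMatrix

# six conditions, four experts; C6 is an MCH condition the panel scored low
scores = np.array(
    [
        [4, 4, 3, 2, 2, 1],
        [4, 3, 3, 3, 2, 1],
        [4, 4, 3, 2, 2, 1],
        [4, 3, 3, 3, 2, 1],
    ],
    dtype=float,
)
matrix = ScoreMatrix(
    expert_ids=("E1", "E2", "E3", "E4"),
    condition_ids=("C1", "C2", "C3", "C4", "C5", "C6"),
    scores=scores,
)
meta = pd.DataFrame(
    {
        "condition_id": ["C1", "C2", "C3", "C4", "C5", "C6"],
        "name": ["tb", "malaria", "anaemia", "diabetes", "asthma", "measles"],
        "gbd_level2": ["infectious"] * 3 + ["ncd"] * 2 + ["infectious"],
        "mch_flag": [False, False, False, False, False, True],
    }
)

table = build_equity_table(matrix, meta)
print(table.round(3).to_string(index=False))
# measles (MCH, scored 1.0 by the panel) is lifted to the high-category
# minimum mean before standardization, so its weight rises accordingly;
# the lowest remaining score maps to weight 1 and the highest to weight 2.
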