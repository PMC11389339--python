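"""Generate a synthetic priority-setting study and write its three tables.

Emulates the real exercise's shape: 28 experts scoring 253 disease
conditions on the 1-4 equity scale, 20 GBD-level-2 cause groups, a subset
of conditions flagged MCH, and ~200 interventions with right-skewed CERs.
"""

from pathlib import Path

import numpy as np

from equicea import panel_io
from equicea.synthetic import SyntheticConfig, gen_interventions, gen_panel

out = Path("scratch/example_study")
out.mkdir(parents=True, exist_ok=True)

config = SyntheticConfig(seed=42)
matrix, meta, latent = gen_panel(config)
interventions = gen_interventions(config, matrix.condition_ids)

panel_io.write_score_sheet(matrix, out / "scores.csv")
panel_io.write_condition_meta(meta, out / "conditions.csv")
panel_io.write_interventions(interventions, out / "interventions.csv")

print(f"score sheet : {matrix.n_experts} experts x {matrix.n_conditions} conditions")
print(f"missing cells: {int(np.isnan(matrix.scores).sum())}")
print(f"MCH-flagged : {int(meta['mch_flag'].sum())} conditions")
print(f"interventions: {len(interventions)}, CER median "
      f"US${interventions['cer'].median():.0f} per DALY averted")
print(f"written to {out}/")
# The latent means are the ground truth the panel's noisy scores estimate;
# downstream examples recover them from the score sheet alone.
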