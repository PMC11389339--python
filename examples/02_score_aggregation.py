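"""Aggregate raw panel scores: condition means and GBD-level-2 averages.

Run examples/01_generate_study.py first (or point the paths at your own
score sheet and condition metadata).
"""

from pathlib import Path

from equicea import panel_io
from equicea.aggregation import group_means, mean_scores, score_distribution

study = Path("scratch/example_study")
matrix = panel_io.read_score_sheet(study / "scores.csv")
meta = panel_io.read_condition_meta(study / "conditions.csv")

summaries = mean_scores(matrix)
lo = summaries.loc[summaries["mean_score"].idxmin()]
hi = summaries.loc[summaries["mean_score"].idxmax()]
print(f"mean equity scores span {lo['mean_score']:.2f} ({lo['condition_id']}) "
      f"to {hi['mean_score']:.2f} ({hi['condition_id']})")

# per-condition score distribution, the bar-chart view of panel agreement
counts = score_distribution(matrix, hi["condition_id"])
print(f"score counts for {hi['condition_id']}: "
      f"1s={counts[0]} 2s={counts[1]} 3s={counts[2]} 4s={counts[3]}")

groups = group_means(summaries, meta)
print(f"\n{len(groups)} GBD-level-2 groups, most to least equity-relevant:")
print(groups.head(5).to_string(index=False))
# A group mean > 3 marks a cause group the panel sees as concentrated among
# the poor and rural residents.
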