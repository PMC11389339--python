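# equicea

Equity-weighted cost-effectiveness analysis for health benefit package
design.

When a country designs an essential health services package, interventions
are conventionally ranked in a league table by their cost-effectiveness
ratio (CER, cost per DALY averted; lower is better). That ranking is blind
to *who* gains the health: a package built on CERs alone can underserve the
poor, rural residents, women and children. `equicea` implements the
quantitative procedure used in the Ethiopian benefit-package revision to
fold equity into the ranking:

1. **Delphi aggregation** — an expert panel scores every disease condition
   on a 1–4 scale (4 = concentrated among the poor and rural residents);
   the per-condition mean over non-missing scores is the condition's raw
   equity score. Conditions are also rolled up into GBD-level-2 cause
   groups.
2. **Categorization** — conditions are sorted by mean score, descending,
   and split into **high / medium / low** tertiles, sized as equally as
   ties allow (tied means never straddle a boundary).
3. **MCH reassignment** — conditions predominantly affecting women of
   reproductive age or under-five children (MCH) that landed in medium or
   low are lifted to the *minimum* mean score of the high category, so that
   maternal and child health counts for more, but never more than the
   attributes the panel scored directly.
4. **Standardization** — post-reassignment scores are min–max rescaled to
   equity weights *w* ∈ [1, 2]:
   `w = 1 + (s − s_min) / (s_max − s_min)`,
   so health gains for the worst-off condition carry twice the weight of
   gains for the best-off.
5. **League reranking** — each intervention inherits its condition's weight
   (mean across conditions when it spans several) and its CER is adjusted
   by multiplying the health-benefit denominator by the weight:
   `CER_adj = CER / w`. A weight of 2 halves the CER; a weight of 1 leaves
   it unchanged. Interventions are re-ranked by adjusted CER and the two
   rankings are compared (entries/exits from the top *k*, per-intervention
   rank shifts, Kendall τ-b).

A synthetic-data module generates panels, metadata and intervention tables
with the structure of the real exercise (28 experts × 253 conditions,
latent condition means spanning ~1.1–3.8, ordinal rater noise, log-normal
CERs), so every stage is testable end to end without any restricted data.

## Worked example

```bash
python examples/01_generate_study.py   # writes scratch/example_study/*.csv
python examples/04_league_reranking.py
```

prints (seed 42):

```
intervention_id  cer  equity_weight  adjusted_cer  rank_cer  rank_adjusted  rank_delta
           I055 1.87           1.68          1.11         1              1           0
           I075 2.18           1.33          1.63         2              2           0
           I185 4.00           1.73          2.31         7              3           4
...
entered top 30 after equity adjustment: ['I112', 'I121']
exited top 30 after equity adjustment : ['I044', 'I151']
Kendall tau-b between rankings        : 0.937
```

I185 treats a condition the panel judged strongly pro-poor (weight 1.73),
so its cost per DALY averted effectively drops from \$4.00 to \$2.31 and it
climbs four places; two interventions against low-weight conditions drop
out of the top 30 to make room. `examples/02_score_aggregation.py` and
`examples/03_equity_weights.py` walk the earlier stages, including how a
low-scored MCH condition (measles, panel mean 1.0) is lifted to the
high-category minimum (3.5) and ends up with weight 1.75 instead of 1.0.

The same pipeline runs from the shell:

```bash
equicea synth --seed 42 --out study/
equicea all --scores study/scores.csv --meta study/conditions.csv \
            --interventions study/interventions.csv --top-k 30 --out run/
equicea report --league run/league_table.csv --top-k 30
```

Inputs are plain CSV: a score sheet (experts as rows, conditions as
columns, blank = abstained), condition metadata
(`condition_id,name,gbd_level2,mch_flag`) and an intervention table
(`intervention_id,name,condition_ids,cer` with `;`-separated condition
lists). All readers validate the schema strictly and every writer
round-trips bit-identically.

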