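# Methods

## The model

The object being estimated is a per-condition *equity score*: how strongly
a disease condition is concentrated among the worse-off (the poor and
rural residents, with women and children handled by a separate rule). The
data are ordinal ratings `x_{ec} ∈ {1,2,3,4}` from expert `e` on condition
`c`, with abstentions allowed. The estimator is the plain mean over
non-missing ratings,

    s_c = mean_e x_{ec},

with no rater weighting, shrinkage, or consensus statistic — the procedure
treats the panel as exchangeable raters, and the package's tests enforce
that exchangeability (permuting experts changes nothing). Multi-round
sheets are pooled into a single matrix upstream; rounds are not modelled.

The downstream transform is deterministic in the `s_c`:

1. **Tertile categorization.** Conditions are sorted by `s_c` descending
   and cut into high/medium/low blocks. The cut may fall only where the
   sorted score strictly decreases, so tied means always share a category.
   Among all admissible cut pairs the one whose block sizes are closest
   (L1) to the equal-count target is used; the target assigns remainder
   conditions to earlier blocks, and residual ambiguity is broken toward
   matching the high-block target first, then the medium. With fewer than
   three distinct values the top-down blocks are filled as far as the tie
   structure allows (all-tied input collapses into a single high block).
   User-supplied score cut-points are available as an alternative to
   tertiles.
2. **MCH reassignment.** Let `h = min{ s_c : c ∈ high }`. Every condition
   flagged as predominantly affecting women or children whose category is
   medium or low gets `s'_c = h`; all others keep `s'_c = s_c`. Because
   every medium/low mean is ≤ h, the rule never lowers a score. `h` is
   always recomputed from the data at hand, never treated as a constant.
3. **Standardization.** `w_c = 1 + (s'_c − min s') / (max s' − min s')`,
   an affine, order-preserving map onto [1, 2]; the bounds encode the
   panel consensus that gains to the worst-off carry twice the weight of
   gains to the best-off. If all `s'_c` coincide there is nothing to
   differentiate: every weight is set to 1 and a warning is logged rather
   than raising, since a constant panel is a legitimate (if uninformative)
   outcome. Reassignment precedes standardization — the weights reflect
   post-reassignment scores.
4. **Equity-adjusted CERs.** An intervention's weight is the unweighted
   mean of its linked conditions' weights (`max`/`min` available as
   options; the choice matters only for multi-condition interventions and
   is recorded in run artifacts). The adjustment multiplies the
   health-benefit denominator by the weight, i.e. `CER_adj = CER / w`, so
   `CER_adj ∈ [CER/2, CER]` always. League ranks are ascending in CER and
   in adjusted CER separately, with ties broken lexicographically by
   intervention id so output is byte-reproducible. Ranking change is
   summarized by top-k entries/exits (default k = 30), signed rank deltas,
   and Kendall τ-b (tie-corrected, via scipy; chosen because adjustment
   can create exact ties).

## Synthetic data

`SyntheticConfig` defaults describe the study the pipeline was built for:
28 experts, 253 conditions, 20 GBD-level-2 groups assigned round-robin,
latent condition means drawn uniformly on [1.1, 3.8] (the realized range
of mean scores in such exercises, so synthetic league tables exercise the
full weight range), and log-normal CERs with log-mean 4.5 and log-sd 1.5
(median ≈ US$90 per DALY averted with a long right tail, typical of
published CER compilations).

The ordinal response model is latent-Gaussian: expert `e`'s rating of
condition `c` is `clip(round(μ_c + ε), 1, 4)` with `ε ~ N(0, σ)`. Default
σ = 0.7 reproduces the visible feature of real panels that a single
condition can draw all four score levels; it is a free parameter because
real rater noise is not identified from published summaries. Cells are
masked missing independently at rate 0.01 (abstentions are rare but
permitted); a condition that would lose all raters keeps one at random so
every condition stays estimable. 15% of conditions are MCH-flagged, giving
a few dozen flags of which a subset lands outside the high tertile — the
population the reassignment rule acts on. Each intervention links to 1–2
conditions sampled without replacement.

This generator emulates dimensions, ordinal noise, missingness and CER
skew. It does **not** emulate expert heterogeneity by profession or
region, correlation between a condition's equity score and its CER, the
multi-round Delphi structure, or any real condition list — so green tests
demonstrate that the procedure is implemented correctly and is recoverable
under its own assumptions, not that any particular country's published
rankings are reproduced.

The model was chosen over a multinomial alternative because it admits a
closed-form oracle: the expected rating is a four-point sum of Gaussian
cell probabilities, which the test suite integrates independently
(scipy.stats.norm) and compares against Monte-Carlo recovery runs. With
zero noise and integer latent means the response model is the identity,
which yields the pipeline's exact parameter-recovery check: equity weights
must equal the min–max transform of the latent means to machine precision.

## Numerical and design choices

- Means and weights are carried at full float precision; any rounding
  (e.g. two decimals in reports) happens only at display time.
- The equal-count-tertile reading of "three groups" is a design choice;
  the published description does not state whether the real groups were
  equal-sized or threshold-cut, which is why `cutpoints=` exists.
- Seeds: all randomness flows through `numpy.random.default_rng`; derived
  streams use tuple seeds `(seed, tag, rep)` so the panel, the
  intervention table and each Monte-Carlo replicate are independent but
  jointly reproducible. Identical config ⇒ bit-identical output, verified
  at file level.
- Degenerate inputs: fewer than 3 conditions cannot be categorized
  (error); an empty high category cannot anchor reassignment (error,
  unreachable under the tertile splitter); an all-tied panel standardizes
  to weight 1 everywhere (warning).
- Problem sizes in the test suite and the acceptance script are the
  study's own dimensions (28 × 253, 200 interventions) for single runs;
  Monte-Carlo recovery uses 100–200 replicates at 28–56 experts × 30–50
  conditions, enough for the ~0.004 standard error the bias oracle
  comparison needs.

## Limitations

- The pipeline reproduces the *mechanism* of the published exercise; the
  exact real-data values (the 253-condition list, the realized 2.25
  high-category minimum, the named top-30 interventions) live in
  supplementary worksheets that are not redistributable, so they appear
  here only as fixture values in tests of the rules themselves.
- Equity is a single composite score; the four underlying attributes
  (income, residence, gender, age) are not modelled separately, and no
  inequality-aversion parameterization (e.g. Atkinson) is offered.
- Financial-risk protection, budget impact and full multi-criteria
  composites are out of scope; CERs are inputs, never estimated.
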