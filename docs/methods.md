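# Methods

## Quantitative profiling and the detection-limit model

Counts are converted to proportions per sample (columns sum to 1), then
scaled by the measured total cell density (cells/mL) assuming one 16S rRNA
gene copy per cell. No copy-number correction is attempted. Pre-imputation
column sums therefore reproduce the measured densities exactly.

Each sample's limit of detection is the abundance equivalent of a single
read: `LOD% = 100 / total_reads` and `LOD_cells = density / total_reads`.
These two are related by `LOD_cells = density × LOD% / 100` identically.
Reported LOD percentages use stepwise half-up rounding — to 4 decimal places
in percent, then to 3 — matching the convention of the published detection
limits this model reproduces (18,197 reads → 0.0055% → 0.006%; 32,779 →
0.003%; 25,621 → 0.004%). One-step rounding to 3 decimals would print 0.005%
for the first case; the stepwise convention is deliberate.

**Imputation.** The "overall LOD" is the *maximum* per-sample LOD of the
analysed sample set, applied uniformly: it is the most conservative
detectable floor, guaranteeing no imputed value sits below any sample's true
detection limit. Entries below it are replaced by it and flagged. A
`per-sample` policy (each sample's own floor) is available behind a switch.
Note that under the overall policy an entry can be lifted even though it was
above its own sample's LOD; the flag matrix records exactly which entries
were touched, and the detection flags used by the consistency rule derive
from it.

**Top-N restriction.** Taxa are ranked by mean absolute abundance across
*all* samples of the dataset (globally, not per donor or condition, for
cross-donor comparability), ties broken toward the lexicographically smaller
taxon id; the 100 most abundant are retained for scoring and testing. The
cap exists to limit the multiple-testing burden.

## Diversity indices and the community modulation score

Observed richness, bias-corrected Chao1 (`S_obs + F1(F1−1)/(2(F2+1))`),
Shannon entropy (natural log) and the reciprocal Simpson index (`1/Σp²`) are
computed on **read counts** via scikit-bio — they are proportional-data
statistics and applying them to density-scaled values would only rescale
their inputs.

The CMS operates on **LOD-imputed absolute abundances** restricted to the
global top-100 set. For each taxon x, strict multiplicative tests:
treatment > control × 1.3 counts +1 (positive CMS); control > treatment ×
1.3 counts −1 (negative CMS); combined = positive + negative. Ties at
exactly 1.3-fold count nothing. The two criteria are deliberately asymmetric
multiplicative tests, not a symmetric log-ratio rule; swapping the arms
negates the combined score and exchanges |positive| with |negative|, and the
score is invariant to scaling both arms by a common factor. The default
threshold 0.30 is twice the 15% technical SD of per-taxon quantitative
detection between replicate bioreactors (`TECHNICAL_CV`), placing a counted
change ≈2 SD beyond technical noise. Per-donor scores are integers;
cross-donor summaries report means (generally non-integers) and SDs (SD 0
by convention for a single donor).

Imputation before scoring is what keeps ratios finite when a taxon is
undetected in one arm; a taxon absent from both arms sits at the floor in
both and scores 0.

## Paired differential testing and consistency classes

Per taxon, treatment vs control across donors is a within-donor paired
location test on log10 LOD-imputed abundances: a two-condition
repeated-measures analysis with donor as subject is algebraically the paired
t-test (F = t²), which is what `scipy.stats.ttest_rel` computes. Effect
sizes are reported as the mean over donors of log2(treatment/control) —
log10 for testing, log2 for reporting. Degenerate difference vectors are not
given fabricated statistics: all-zero differences get p = 1, a constant
non-zero shift gets p = 0, both flagged; fewer than 3 complete donor pairs
leaves p undefined (NaN, flagged). Benjamini–Hochberg correction
(statsmodels) is applied per treatment contrast across the retained taxa,
significance at FDR 0.20.

Non-significant taxa are classed as consistent responders when detected
(above the LOD in either arm, i.e. not imputed in both) in at least 4 of the
6 donors and moving in the same direction in *every* donor where detected.
"Either arm above LOD" is this package's operationalisation of "present";
the classification is exclusive and exhaustive (significant_up/down,
consistent_up/down, none). Family-level analysis sums member taxa (lineage
rank `f__`, else the 5th semicolon field, else "unclassified"), preserving
column totals so the same machinery applies.

## The synthetic experiment generator

The generator emulates a 6-donor × 3-condition (NSC / inulin / dextran)
parallel-bioreactor study; its defaults are the emulated study's conditions:
densities 3.0×10⁹ (NSC), 7.8×10⁹ (inulin), 8.3×10⁹ (dextran) cells/mL; mean
read depths 18,197 / 32,779 / 25,621; 120 taxa (≥100 analysed); 15%
per-taxon technical CV; dextran planting 22 taxa up / 5 down and inulin 9 up
/ 14 down at |log2FC| = 1.

* **Baselines.** Three family-level enterotype templates
  (Lachnospiraceae+Methanobacteriaceae-, Prevotellaceae- and
  Bacteroidaceae-dominated) are assigned round-robin, so donor pairs share a
  template as in the emulated cohort. Within each family, per-donor taxon
  weights are log-normal with log-SD `composition_sigma` (default 1.0,
  a typical breadth for within-family abundance spread), renormalised so
  family totals equal the template weights; profiles sum to 1 exactly.
  `composition_sigma` is separate from `technical_cv` by design: the former
  is biology (who lives there), the latter measurement.
* **Effects.** Planted taxa multiply their relative weight by 2^log2FC, then
  the arm is rescaled to its drawn density (default mode). In this mode the
  *realised* absolute fold change of a planted taxon is `2^lfc × (D_t/D_c) / T`
  where T is the planted biomass factor — so untouched taxa also shift by
  `(D_t/D_c)/T`. The alternative `absorb_planted_biomass` mode sets the
  treatment's true density to the control draw × T instead: responder growth
  *is* the biomass gain, untouched taxa keep their absolute levels exactly,
  and planted folds equal 2^lfc. The absorb mode mirrors how substrate-driven
  blooms raise measured cell density in real fermentations and is what the
  controlled recovery configurations use; the fixed-density mode remains the
  default because the per-condition density targets are then honoured
  exactly.
* **Noise.** Sequencing: per-taxon mean-1 log-normal factors with SD
  `technical_cv` on the true relative abundances, renormalised, then one
  multinomial draw at a depth drawn negative-binomially around the
  condition mean (depth CV 10% by default; the emulated study reports only
  means, so within-condition spread is a configurable placeholder, as is
  the 10% density CV). Flow cytometry: true density × mean-1 log-normal
  noise with SD `density_cv`. All log-normals are mean-corrected so
  arithmetic means equal their targets.
* **Determinism.** Every stage consumes a child stream of `rng_seed`;
  identical configs give bit-identical experiments.

**Controlled configurations.** `responder_config(n_up, n_down)` plants
random taxa at ±1 log2FC in a 100-taxon community with `absorb_planted_biomass`,
density noise off and study-like depths — under these conditions the sign of
the mean combined CMS over ≥50 donors recovers the planted balance (+ for
22/5, − for 9/14). Two caveats shape that design. First, under the
fixed-density mode a treatment that raises density ~2.7-fold lifts
essentially every taxon past the 130% rule (combined CMS ≈ +95 on default
study runs), and conversely planting 22 random taxa up at *equal* densities
drags the 73 untouched taxa to a fold of ~0.83, producing a *negative* mean
combined score; neither regime can distinguish the 22/5 from the 9/14
profile. Second, density noise is a coherent per-sample factor — it moves
all 100 taxa of a donor together — and at 10% CV it swamps the small 9−14
planted signal. `null_config` (no effects, equal noise-free densities) is
the matching null: its mean combined CMS is 0 within Monte-Carlo error, and
on a flat community the per-taxon false-increase probability matches the
analytic upper tail of the technical+counting noise ratio at the 1.3-fold
threshold (~11% at depth 25,000 — larger than the 2-SD heuristic suggests,
because two noisy arms enter the ratio).

**What the generator does not model**, and hence what passing tests do not
show about real data: compositional correlations between taxa beyond the
family constraint, donor-specific substrate responses, cross-feeding,
growth kinetics, chimeras/contamination, or 16S copy-number variation.
Metabolite tables are condition-shifted Gaussians (CV 8%) with means chosen
to reproduce realistic contrasts (~25% more propionate and ~31% less gas
for dextran vs inulin, valerate depressed by inulin, bCFA lowered and pH
dropped by both treatments); no fermentation chemistry is modelled.

## Fermentation summaries

Total SCFA = acetate + propionate + butyrate + valerate; bCFA = isobutyrate
\+ isocaproate + isovalerate; propionate:acetate requires positive acetate.
Percent differences between two conditions pair donors present in both and
default to the ratio of cross-donor means, `100 × (mean_a − mean_b)/mean_b`
(robust to small denominators; mean-of-ratios available by flag). Paired
significance reuses the same paired machinery as the taxon contrasts without
the log transform, since pH and pressure are not log-scale quantities.

## Numerical choices and limitations

* Strict inequalities at the 1.3-fold CMS boundary; exact ties score 0.
* Half-up (not banker's) rounding for reported LOD percentages.
* Printed cells/mL detection limits elsewhere in the literature are
  sometimes internally inconsistent with the defining formula; this package
  always computes `density / total_reads` and treats percentage limits as
  the reporting quantity.
* BH q-values propagate NaN for degenerate tests rather than excluding taxa
  silently; degenerate flags travel with the effect table.
* Problem sizes in the test and acceptance suites (50-donor recovery runs,
  200-donor null, depth 25,000) keep Monte-Carlo error well below the
  effects being detected (SEM < 1 CMS unit) while the full suite runs in
  seconds.
* The pipeline starts at the OTU count table: no FASTQ processing, OTU
  calling, rarefaction, ordination or regularised correlation analyses are
  provided; the effect table export is the interface to downstream
  visualisation tools.
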