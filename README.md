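# quantbiome

Quantitative microbiome profiling (QMP) and the **community modulation
score (CMS)** for parallel ex vivo gut fermentation experiments, with an
explicit limit-of-detection model, traditional α-diversity indices, paired
differential-response testing, and a synthetic experiment generator with
known ground truth.

## The problem

In ex vivo fermentation screens, faecal microbiota from several donors are
incubated with and without a test substrate (e.g. a prebiotic fibre) and
profiled by 16S rRNA gene sequencing. Sequencing alone yields *proportions*,
and proportional α-diversity indices mislead in two ways when a substrate
boosts growth: (i) they ignore that total biomass changed, and (ii) a denser
community has a *higher* detection limit — with the same read depth each
read represents more cells, so rare taxa vanish from view and apparent
richness falls even when nothing was lost.

`quantbiome` implements the quantitative alternative. Relative abundances
are scaled by flow-cytometry total cell counts (one 16S copy per cell
assumed) to estimated absolute abundances,

```
cells/mL(taxon, sample) = proportion(taxon, sample) × total_density(sample)
```

with a per-sample limit of detection `LOD = density / total_reads` (as a
percentage, `100 / total_reads`). Sub-LOD values are imputed at the overall
LOD so log-scale statistics stay finite. On this quantitative scale the
community modulation score counts, among the 100 most abundant taxa, those
that truly changed versus the no-substrate control (NSC):

```
positive CMS = #{x : OTU_x^treatment > OTU_x^NSC × 130%}
negative CMS = −#{x : OTU_x^NSC > OTU_x^treatment × 130%}
combined CMS = positive CMS + negative CMS
```

The 30% threshold is twice the ~15% technical standard deviation of
per-taxon quantitative detection between replicate bioreactors, so a counted
change is ≈2 SD beyond technical noise. A positive combined CMS marks a
treatment that raised more taxa than it suppressed — a diversity booster in
the quantitative sense.

Around the score, the package provides Chao1 / Shannon / inverse-Simpson
indices (on read counts, where they belong), paired repeated-measures
testing of log10 abundances across donors with Benjamini–Hochberg FDR
control (0.20), a "consistent responder" rule for taxa detected in ≥4 of 6
donors that move the same way in all of them, fermentation endpoint
summaries (total SCFA, bCFA, propionate:acetate, paired percent
differences), and a seeded synthetic generator emulating a 6-donor ×
3-condition (NSC / inulin / dextran) study with planted per-taxon fold
changes for recovery testing.

## Worked example

```python
from quantbiome import (study_config, generate_experiment, quantitative_profile,
                        impute_below_lod, select_top_n, cms_scores, cms_summary)

counts, metadata, densities, truth = generate_experiment(study_config(seed=1, n_taxa=100))
matrix = impute_below_lod(quantitative_profile(counts, densities))
matrix = matrix.subset_taxa(select_top_n(matrix, 100))
print(cms_summary(cms_scores(matrix, metadata, control="NSC")))
```

prints

```
condition  n_donors  mean_positive  sd_positive  mean_negative  sd_negative  mean_combined  sd_combined
  dextran         6           95.0         1.79          -0.33         0.52          94.67         2.16
   inulin         6           93.0         2.53          -0.17         0.41          92.83         2.71
```

Here both treatments raise total density ~2.6-fold, so nearly all of the
top-100 taxa exceed the 130% rule and the combined CMS is strongly positive;
contrast this with the proportional Shannon index on the same run, which
*drops* slightly under treatment (4.15 → 4.09–4.12). The detection-limit
arithmetic for the emulated mean read depths:

```python
from quantbiome import lod_percent_reported, sample_lod
lod_percent_reported(18197)   # 0.006  (% of community, NSC)
lod_percent_reported(32779)   # 0.003  (inulin)
sample_lod(18197, 3.0e9)      # 164862.9... cells/mL
```

The `examples/` scripts each demonstrate one capability end to end
(simulation, quantitative profiling, CMS vs α-diversity, responder
recovery, fermentation summaries) and print annotated numbers. A thin CLI
mirrors the stages:

```bash
quantbiome simulate --outdir demo --seed 3 --taxa 100
quantbiome run --outdir demo_out --synthetic-seed 3
```

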