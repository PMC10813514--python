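"""Traditional alpha diversity versus the community modulation score (CMS).

Proportional diversity indices drop under treatments that raise biomass
(higher detection limit, selective blooms), while the CMS counts how many of
the top-100 taxa truly rose or fell in absolute abundance (cells/mL) by more
than 30% versus the no-substrate control.
"""

from quantbiome import (
    alpha_diversity_table,
    cms_scores,
    cms_summary,
    generate_experiment,
    impute_below_lod,
    quantitative_profile,
    select_top_n,
    study_config,
)

counts, metadata, densities, _ = generate_experiment(study_config(seed=1, n_taxa=100))

alpha = alpha_diversity_table(counts.counts)
print("mean alpha diversity by condition (read counts):")
print(alpha.groupby(metadata["condition"]).mean().round(2))

matrix = impute_below_lod(quantitative_profile(counts, densities))
matrix = matrix.subset_taxa(select_top_n(matrix, 100))
scores = cms_scores(matrix, metadata, control="NSC")
print("\ncommunity modulation scores (per donor, top-100 taxa, 30% threshold):")
print(scores.head(4).to_string(index=False))
print("\ncross-donor summary:")
print(cms_summary(scores).round(2).to_string(index=False))
# A positive mean combined CMS means the treatment raised more taxa than it
# suppressed -- a diversity booster in the quantitative sense.
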