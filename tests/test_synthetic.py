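import dataclasses

import numpy as np
import pandas as pd
import pytest

from quantbiome.synthetic import (
    CONTROL,
    EffectSpec,
    SyntheticConfig,
    apply_effects,
    assign_taxa,
    generate_baseline,
    generate_experiment,
    simulate_cell_counts,
    simulate_fermentation,
    simulate_sequencing,
    study_config,
)

TWO_TAXON_TEMPLATE = {"flat": {"Lachnospiraceae": 0.5, "Bacteroidaceae": 0.5}}


def flat_config(**overrides) -> SyntheticConfig:
    defaults = dict(
        n_donors=4,
        n_taxa=10,
        enterotype_templates={"flat": {"Lachnospiraceae": 1.0}},
        composition_sigma=0.0,
        density_cv=0.0,
        technical_cv=0.0,
        read_depth_cv=0.0,
        treatment_density_mean={"treatment": 3.0e9},
        read_depth_mean={CONTROL: 1000, "treatment": 1000},
        rng_seed=5,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


class TestBaseline:
    def test_degenerate_config_gives_identical_uniform_profiles(self):
        base = generate_baseline(flat_config())
        expected = np.full((10, 4), 0.1)
        np.testing.assert_allclose(base.to_numpy(), expected)

    def test_columns_sum_to_one(self):
        base = generate_baseline(study_config(seed=3))
        np.testing.assert_allclose(base.sum(axis=0), 1.0, atol=1e-9)

    def test_dominant_family_matches_assigned_template(self):
        cfg = study_config(seed=8, n_taxa=100)
        base = generate_baseline(cfg)
        roster = assign_taxa(cfg).set_index("taxon_id")
        template_names = list(cfg.enterotype_templates)
        for i, donor in enumerate(base.columns):
            family_totals = base[donor].groupby(roster["family"]).sum()
            expected_family = template_names[i % 3].replace("_rich", "")
            assert family_totals.idxmax() == expected_family

    def test_seeded_determinism(self):
        cfg = study_config(seed=21)
        a = generate_baseline(cfg)
        b = generate_baseline(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="template support"):
            generate_baseline(study_config(seed=0, n_taxa=5))


class TestApplyEffects:
    def test_no_effects_equal_densities_makes_arms_identical(self):
        cfg = flat_config()
        truth = apply_effects(generate_baseline(cfg), cfg)
        for d in range(1, 5):
            np.testing.assert_allclose(
                truth.true_abundance[f"D{d}_treatment"],
                truth.true_abundance[f"D{d}_NSC"],
            )

    def test_two_taxon_hand_case(self):
        # one taxon planted at log2FC=1 in a 50/50 community, equal densities:
        # post-renormalization abundance ratios are (2/1.5, 1/1.5)
        cfg = flat_config(n_taxa=2, enterotype_templates=TWO_TAXON_TEMPLATE)
        taxa = assign_taxa(cfg)["taxon_id"].tolist()
        cfg = dataclasses.replace(
            cfg, effect_specs=(EffectSpec("treatment", (taxa[0],), 1.0),)
        )
        truth = apply_effects(generate_baseline(cfg), cfg)
        fc = truth.true_fold_change("D1", "treatment")
        np.testing.assert_allclose(fc[taxa[0]], 2 / 1.5)
        np.testing.assert_allclose(fc[taxa[1]], 1 / 1.5)

    def test_pure_density_scaling(self):
        cfg = flat_config(treatment_density_mean={"treatment": 6.0e9})
        truth = apply_effects(generate_baseline(cfg), cfg)
        fc = truth.true_fold_change("D1", "treatment")
        np.testing.assert_allclose(fc, 2.0)

    def test_column_sums_equal_true_density(self):
        cfg = study_config(seed=2)
        truth = apply_effects(generate_baseline(cfg), cfg)
        np.testing.assert_allclose(
            truth.true_abundance.sum(axis=0),
            truth.true_density[truth.true_abundance.columns],
            rtol=1e-9,
        )

    def test_absorbed_biomass_conserves_non_planted_taxa(self):
        cfg = flat_config(absorb_planted_biomass=True)
        taxa = assign_taxa(cfg)["taxon_id"].tolist()
        cfg = dataclasses.replace(
            cfg, effect_specs=(EffectSpec("treatment", tuple(taxa[:3]), 1.0),)
        )
        truth = apply_effects(generate_baseline(cfg), cfg)
        fc = truth.true_fold_change("D1", "treatment")
        np.testing.assert_allclose(fc[taxa[:3]], 2.0)
        np.testing.assert_allclose(fc[taxa[3:]], 1.0)

    def test_unknown_planted_taxon_rejected(self):
        cfg = flat_config()
        cfg = dataclasses.replace(
            cfg, effect_specs=(EffectSpec("treatment", ("NOPE",), 1.0),)
        )
        with pytest.raises(ValueError, match="unknown taxa"):
            apply_effects(generate_baseline(cfg), cfg)

    def test_effect_on_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            EffectSpec(CONTROL, ("OTU001",), 1.0)


class TestSequencing:
    def test_depth_one_yields_single_read(self):
        cfg = flat_config(read_depth_mean={CONTROL: 100, "treatment": 100})
        truth = apply_effects(generate_baseline(cfg), cfg)
        rng = np.random.default_rng(0)
        counts = {}
        for sample in truth.true_abundance.columns:
            rel = truth.true_abundance[sample] / truth.true_abundance[sample].sum()
            counts[sample] = rng.multinomial(1, rel)
        assert all(c.sum() == 1 and (c == 1).sum() == 1 for c in counts.values())

    def test_high_depth_proportions_converge_to_truth(self):
        depth = 10**6
        cfg = flat_config(
            n_donors=1,
            composition_sigma=0.5,
            read_depth_mean={CONTROL: depth, "treatment": depth},
        )
        truth = apply_effects(generate_baseline(cfg), cfg)
        counts = simulate_sequencing(truth, cfg)
        for sample in counts.sample_ids:
            p = truth.true_abundance[sample] / truth.true_abundance[sample].sum()
            phat = counts.counts[sample] / counts.counts[sample].sum()
            bound = 3 * np.sqrt(p * (1 - p) / depth)
            assert (np.abs(phat - p) <= bound + 1e-12).all()

    def test_binomial_expectation_on_even_community(self):
        cfg = flat_config(
            n_donors=1,
            n_taxa=2,
            enterotype_templates=TWO_TAXON_TEMPLATE,
            read_depth_mean={CONTROL: 1000, "treatment": 1000},
        )
        truth = apply_effects(generate_baseline(cfg), cfg)
        rng = np.random.default_rng(7)
        means = []
        for _ in range(300):
            counts = simulate_sequencing(truth, cfg, rng=rng)
            means.append(counts.counts.iloc[0, 0])
        # binomial(1000, 0.5): mean 500, MC error 3*sqrt(250/300) < 3
        assert abs(np.mean(means) - 500) < 3 * np.sqrt(250 / 300)

    def test_column_sums_equal_realized_depths(self, study_experiment):
        counts = study_experiment.counts
        assert (counts.counts.sum(axis=0) == counts.total_reads()).all()


class TestCellCounts:
    def test_zero_cv_measures_truth_exactly(self):
        cfg = flat_config()
        truth = apply_effects(generate_baseline(cfg), cfg)
        measured = simulate_cell_counts(truth, cfg)
        pd.testing.assert_series_equal(
            measured, truth.true_density, check_names=False
        )

    def test_nsc_density_mean_recovered_over_many_donors(self):
        cfg = study_config(seed=13, n_donors=150)
        truth = apply_effects(generate_baseline(cfg), cfg)
        measured = simulate_cell_counts(truth, cfg)
        nsc = measured[truth.metadata.index[truth.metadata["condition"] == CONTROL]]
        # lognormal, CV 0.10 twice (draw + measurement): SEM ~ 3e9*0.15/sqrt(150)
        assert abs(nsc.mean() - 3.0e9) < 3 * 3.0e9 * 0.15 / np.sqrt(150)


class TestExperiment:
    def test_study_layout_has_18_samples(self, study_experiment):
        counts, metadata, densities, truth = study_experiment
        assert len(metadata) == 18
        assert metadata["donor"].nunique() == 6
        assert set(metadata["condition"]) == {"NSC", "inulin", "dextran"}
        assert list(counts.counts.columns) == list(metadata.index)
        assert list(truth.true_abundance.columns) == list(metadata.index)
        assert set(densities.index) == set(metadata.index)

    def test_minimal_run_completes(self):
        cfg = flat_config(
            n_donors=1, n_taxa=2, enterotype_templates=TWO_TAXON_TEMPLATE
        )
        exp = generate_experiment(cfg)
        assert exp.counts.counts.shape == (2, 2)

    def test_end_to_end_determinism(self):
        cfg = study_config(seed=42)
        a = generate_experiment(cfg)
        b = generate_experiment(cfg)
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
        pd.testing.assert_series_equal(a.densities, b.densities)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_donors=0)
        with pytest.raises(ValueError):
            SyntheticConfig(technical_cv=-0.1)
        with pytest.raises(ValueError):
            SyntheticConfig(read_depth_mean={CONTROL: 50, "inulin": 200, "dextran": 200})
        with pytest.raises(ValueError):
            SyntheticConfig(nsc_density_mean=0.0)


class TestFermentationGenerator:
    def test_table_covers_samples_and_ranges(self, study_experiment):
        table = simulate_fermentation(study_experiment.metadata, rng=3)
        assert list(table.index) == list(study_experiment.metadata.index)
        assert (table.drop(columns="pH") >= 0).all().all()
        assert table["pH"].between(0, 14).all()

    def test_condition_shift_visible(self, study_experiment):
        table = simulate_fermentation(study_experiment.metadata, rng=3)
        by_cond = table.groupby(study_experiment.metadata["condition"]).mean()
        assert by_cond.loc["inulin", "gas_pressure"] > by_cond.loc["NSC", "gas_pressure"]
        assert by_cond.loc["dextran", "propionate"] > by_cond.loc["inulin", "propionate"]
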