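"""Synthetic ex vivo fermentation experiments with known ground truth.

The generator emulates a parallel-bioreactor study: faecal inocula from
``n_donors`` adults spanning enterotype-like composition differences are
incubated without substrate (the no-substrate control, NSC) and with one or
more test substrates, then profiled by 16S sequencing plus flow-cytometry
total cell counts.  Defaults mirror the emulated study design: 6 donors,
conditions NSC / inulin / dextran, total densities near 3.0e9 (NSC), 7.8e9
(inulin) and 8.3e9 (dextran) cells/mL, mean read depths 18,197 / 32,779 /
25,621, >=100 taxa, 15% per-taxon multiplicative technical noise, and one
16S rRNA gene copy per cell.

Donor baselines are built from family-level enterotype weight templates
(Prevotellaceae-, Bacteroidaceae- or Lachnospiraceae/Methanobacteriaceae-
dominated), assigned round-robin; within each family, per-donor taxon weights
are log-normal.  Treatment effects are planted as per-taxon fold changes on
the relative composition, after which each arm is rescaled to its drawn total
density — so the planted fold change plus the density ratio together define
each taxon's true absolute fold change (available in :class:`GroundTruth`
for recovery testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import CountTable

__all__ = [
    "EffectSpec",
    "SyntheticConfig",
    "GroundTruth",
    "Experiment",
    "default_templates",
    "study_config",
    "responder_config",
    "null_config",
    "assign_taxa",
    "generate_baseline",
    "apply_effects",
    "simulate_sequencing",
    "simulate_cell_counts",
    "generate_experiment",
    "simulate_fermentation",
]

CONTROL = "NSC"

# Family-level enterotype templates: weights renormalized to 1 at use.
# Donor pairs in the emulated study were dominated by Lachnospiraceae +
# Methanobacteriaceae (donors 1/2), Prevotellaceae (3/4) or Bacteroidaceae (5/6).
_BASE_FAMILIES = {
    "Lachnospiraceae": 0.18,
    "Bacteroidaceae": 0.14,
    "Prevotellaceae": 0.08,
    "Ruminococcaceae": 0.14,
    "Bifidobacteriaceae": 0.09,
    "Veillonellaceae": 0.06,
    "Tannerellaceae": 0.05,
    "Erysipelotrichaceae": 0.05,
    "Acidaminococcaceae": 0.04,
    "Coriobacteriaceae": 0.05,
    "Enterobacteriaceae": 0.04,
    "Methanobacteriaceae": 0.03,
    "Sutterellaceae": 0.05,
}


def default_templates() -> dict[str, dict[str, float]]:
    """Three enterotype-like family weight profiles."""
    lachno = dict(_BASE_FAMILIES, Lachnospiraceae=0.34, Methanobacteriaceae=0.08)
    prevo = dict(_BASE_FAMILIES, Prevotellaceae=0.34)
    bacter = dict(_BASE_FAMILIES, Bacteroidaceae=0.34)
    return {
        "Lachnospiraceae_rich": lachno,
        "Prevotellaceae_rich": prevo,
        "Bacteroidaceae_rich": bacter,
    }


@dataclass(frozen=True)
class EffectSpec:
    """A planted treatment effect: taxa shifted by a common log2 fold change."""

    condition: str
    taxon_ids: tuple[str, ...]
    log2_fold_change: float

    def __post_init__(self) -> None:
        if self.condition == CONTROL:
            raise ValueError("effects cannot target the control condition")


@dataclass
class SyntheticConfig:
    """Parameters of one simulated fermentation experiment.

    ``treatment_density_mean`` and ``read_depth_mean`` are per-condition
    dicts; the control's depth comes from ``read_depth_mean[CONTROL]``.
    ``technical_cv`` is the SD (fraction of the mean) of the multiplicative
    per-taxon noise applied before sequencing; ``density_cv`` governs both
    biological spread of true densities around the condition mean and the
    flow-cytometry measurement noise; ``composition_sigma`` is the log-scale
    SD of within-family taxon weights in donor baselines.
    """

    n_donors: int = 6
    n_taxa: int = 120
    enterotype_templates: dict[str, dict[str, float]] = field(
        default_factory=default_templates
    )
    nsc_density_mean: float = 3.0e9
    treatment_density_mean: dict[str, float] = field(
        default_factory=lambda: {"inulin": 7.8e9, "dextran": 8.3e9}
    )
    density_cv: float = 0.10
    read_depth_mean: dict[str, float] = field(
        default_factory=lambda: {CONTROL: 18197, "inulin": 32779, "dextran": 25621}
    )
    read_depth_cv: float = 0.10
    technical_cv: float = 0.15
    composition_sigma: float = 1.0
    effect_specs: tuple[EffectSpec, ...] = ()
    absorb_planted_biomass: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1 or self.n_taxa < 1:
            raise ValueError("counts must be >= 1")
        for cv in (self.density_cv, self.read_depth_cv, self.technical_cv,
                   self.composition_sigma):
            if cv < 0:
                raise ValueError("CVs must be non-negative")
        if self.nsc_density_mean <= 0 or any(
            d <= 0 for d in self.treatment_density_mean.values()
        ):
            raise ValueError("densities must be positive")
        if any(m < 100 for m in self.read_depth_mean.values()):
            raise ValueError("read_depth_mean must be >= 100")
        if CONTROL not in self.read_depth_mean:
            raise ValueError(f"read_depth_mean must include {CONTROL!r}")
        missing = set(self.treatment_density_mean) - set(self.read_depth_mean)
        if missing:
            raise ValueError(f"read_depth_mean missing conditions {sorted(missing)}")

    @property
    def conditions(self) -> list[str]:
        return [CONTROL, *self.treatment_density_mean]


def study_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default study-emulating configuration with planted responder sets.

    Per the emulated responder structure: dextran raises a broad set (22 taxa
    up, 5 down), inulin a narrow one (9 up, 14 down), |log2FC| = 1.  Planted
    sets are drawn from the taxon list reproducibly from ``seed``.
    """
    cfg = SyntheticConfig(rng_seed=seed, **overrides)
    taxa = assign_taxa(cfg)["taxon_id"].tolist()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xEFFEC7]))
    specs = []
    for condition, n_up, n_down in [("dextran", 22, 5), ("inulin", 9, 14)]:
        if condition not in cfg.treatment_density_mean:
            continue
        chosen = rng.choice(taxa, size=n_up + n_down, replace=False)
        specs.append(EffectSpec(condition, tuple(chosen[:n_up]), 1.0))
        specs.append(EffectSpec(condition, tuple(chosen[n_up:]), -1.0))
    return replace(cfg, effect_specs=tuple(specs))


def responder_config(
    n_up: int,
    n_down: int,
    log2_fold_change: float = 1.0,
    n_donors: int = 50,
    seed: int = 0,
    condition: str = "treatment",
) -> SyntheticConfig:
    """A controlled responder-recovery experiment: one treatment, planted taxa.

    ``n_up``/``n_down`` randomly chosen taxa (from ``seed``) are planted at
    +/-``log2_fold_change``; responder biomass is absorbed into the treatment
    density (non-planted taxa keep their absolute levels) and densities are
    drawn without noise, so the CMS sign is driven by the planted counts
    against 15% technical noise at study-like read depths.
    """
    cfg = SyntheticConfig(
        n_donors=n_donors,
        n_taxa=100,
        density_cv=0.0,
        treatment_density_mean={condition: 3.0e9},
        read_depth_mean={CONTROL: 18197, condition: 25621},
        absorb_planted_biomass=True,
        rng_seed=seed,
    )
    taxa = assign_taxa(cfg)["taxon_id"].tolist()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E5b0]))
    chosen = rng.choice(taxa, size=n_up + n_down, replace=False)
    specs = []
    if n_up:
        specs.append(EffectSpec(condition, tuple(chosen[:n_up]), log2_fold_change))
    if n_down:
        specs.append(EffectSpec(condition, tuple(chosen[n_up:]), -log2_fold_change))
    return replace(cfg, effect_specs=tuple(specs))


def null_config(
    n_donors: int = 200, seed: int = 0, depth: int = 25000, uniform: bool = False
) -> SyntheticConfig:
    """A no-effect experiment with equal arm densities, for CMS calibration.

    ``uniform=True`` collapses the community to a flat 100-taxon profile
    (one template, no within-family scatter), which makes the per-taxon noise
    analytically tractable.
    """
    kwargs = {}
    if uniform:
        kwargs = {
            "enterotype_templates": {"flat": {"Lachnospiraceae": 1.0}},
            "composition_sigma": 0.0,
        }
    return SyntheticConfig(
        n_donors=n_donors,
        n_taxa=100,
        density_cv=0.0,
        treatment_density_mean={"treatment": 3.0e9},
        read_depth_mean={CONTROL: depth, "treatment": depth},
        rng_seed=seed,
        **kwargs,
    )


@dataclass
class GroundTruth:
    """The generator's planted truth, for recovery testing."""

    true_abundance: pd.DataFrame  # taxa x samples, cells/mL
    true_density: pd.Series  # per sample, cells/mL
    planted_effects: dict[str, pd.Series]  # condition -> per-taxon log2FC
    metadata: pd.DataFrame  # sample -> donor, condition

    def true_fold_change(self, donor: str, condition: str) -> pd.Series:
        """Realized absolute fold change of every taxon vs this donor's control."""
        meta = self.metadata
        t = meta.index[(meta["donor"] == donor) & (meta["condition"] == condition)][0]
        c = meta.index[(meta["donor"] == donor) & (meta["condition"] == CONTROL)][0]
        return self.true_abundance[t] / self.true_abundance[c]


class Experiment(NamedTuple):
    counts: CountTable
    metadata: pd.DataFrame
    densities: pd.Series
    truth: GroundTruth


def _lognormal_factors(rng, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and SD ~ cv."""
    if cv == 0:
        return np.ones(() if size is None else size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def _lognormal_around(rng, mean: float, cv: float, size=None):
    """Log-normal draw with the requested arithmetic mean and CV."""
    return mean * _lognormal_factors(rng, cv, size)


def assign_taxa(config: SyntheticConfig) -> pd.DataFrame:
    """Deterministic taxon roster: ids, family membership, lineage strings.

    Taxa are apportioned across families proportionally to the average
    template weight (at least one per family).
    """
    templates = config.enterotype_templates
    families = sorted({f for t in templates.values() for f in t})
    if config.n_taxa < len(families):
        raise ValueError(
            f"n_taxa={config.n_taxa} smaller than template support ({len(families)} families)"
        )
    avg = np.array(
        [np.mean([t.get(f, 0.0) for t in templates.values()]) for f in families]
    )
    avg = avg / avg.sum()
    alloc = np.maximum(1, np.floor(avg * config.n_taxa).astype(int))
    # distribute the remainder to the largest families
    while alloc.sum() < config.n_taxa:
        alloc[np.argmax(avg - alloc / config.n_taxa)] += 1
    while alloc.sum() > config.n_taxa:
        i = np.argmax(np.where(alloc > 1, alloc / config.n_taxa - avg, -np.inf))
        alloc[i] -= 1
    rows = []
    k = 1
    for fam, n in zip(families, alloc):
        for _ in range(n):
            rows.append(
                {
                    "taxon_id": f"OTU{k:03d}",
                    "family": fam,
                    "taxonomy": f"d__Bacteria;p__p;c__c;o__o;f__{fam};g__g;s__OTU{k:03d}",
                }
            )
            k += 1
    return pd.DataFrame(rows)


def generate_baseline(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-donor baseline relative-abundance vectors (taxa x donors).

    Donors receive enterotype templates round-robin.  Within each family the
    taxon weights are log-normal (per donor), renormalized so family totals
    match the template weights; every column sums to 1.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    roster = assign_taxa(config)
    template_names = list(config.enterotype_templates)
    cols = {}
    for d in range(config.n_donors):
        template = config.enterotype_templates[template_names[d % len(template_names)]]
        total_w = sum(template.values())
        profile = np.zeros(len(roster))
        for fam, members in roster.groupby("family").groups.items():
            w = template.get(fam, 0.0) / total_w
            if w == 0:
                continue
            g = rng.lognormal(0.0, config.composition_sigma, size=len(members))
            profile[np.asarray(members)] = w * g / g.sum()
        cols[f"D{d + 1}"] = profile / profile.sum()
    return pd.DataFrame(cols, index=roster["taxon_id"].to_numpy())


def apply_effects(
    baseline: pd.DataFrame,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Build true per-sample abundance profiles from baselines.

    Control arm: baseline x that sample's drawn NSC density.  Treatment arms:
    planted taxa are multiplied by 2^log2FC on the relative scale, then the
    column is rescaled so its total equals the condition's density draw.

    With ``config.absorb_planted_biomass`` the treatment density is instead
    the donor's control density times the biomass factor of the planted
    effects — responder growth raises total biomass while non-planted taxa
    keep their absolute levels exactly, the way substrate-driven blooms raise
    measured cell density in real fermentations.  ``treatment_density_mean``
    is then ignored for effect-bearing arms.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))
    unknown = [
        t
        for spec in config.effect_specs
        for t in spec.taxon_ids
        if t not in baseline.index
    ]
    if unknown:
        raise ValueError(f"effect specs target unknown taxa: {unknown[:5]}")
    cols, dens, meta = {}, {}, []
    means = {CONTROL: config.nsc_density_mean, **config.treatment_density_mean}
    for donor in baseline.columns:
        control_density = None
        for condition in config.conditions:
            sample = f"{donor}_{condition}"
            factors = pd.Series(1.0, index=baseline.index)
            for spec in config.effect_specs:
                if spec.condition == condition:
                    factors[list(spec.taxon_ids)] *= 2.0**spec.log2_fold_change
            shifted = baseline[donor] * factors
            if condition == CONTROL:
                density = float(
                    _lognormal_around(rng, means[condition], config.density_cv)
                )
                control_density = density
            elif config.absorb_planted_biomass:
                density = control_density * float(shifted.sum())
            else:
                density = float(
                    _lognormal_around(rng, means[condition], config.density_cv)
                )
            cols[sample] = shifted / shifted.sum() * density
            dens[sample] = density
            meta.append({"sample_id": sample, "donor": donor, "condition": condition})
    planted = {}
    for condition in config.treatment_density_mean:
        lfc = pd.Series(0.0, index=baseline.index)
        for spec in config.effect_specs:
            if spec.condition == condition:
                lfc[list(spec.taxon_ids)] += spec.log2_fold_change
        planted[condition] = lfc
    metadata = pd.DataFrame(meta).set_index("sample_id")
    return GroundTruth(
        true_abundance=pd.DataFrame(cols),
        true_density=pd.Series(dens, name="true_density"),
        planted_effects=planted,
        metadata=metadata,
    )


def _draw_depth(rng, mean: float, cv: float) -> int:
    """Negative-binomial depth draw around the condition mean (CV configurable)."""
    if cv == 0:
        return max(1, int(round(mean)))
    var = (cv * mean) ** 2
    if var <= mean:  # under-dispersed target: fall back to Poisson
        return max(1, int(rng.poisson(mean)))
    p = mean / var
    n = mean * p / (1 - p)
    return max(1, int(rng.negative_binomial(n, p)))


def simulate_sequencing(
    truth: GroundTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> CountTable:
    """Multinomial read sampling with per-taxon log-normal technical noise.

    Per sample: true relative abundances are perturbed by mean-1 log-normal
    factors with SD ``technical_cv`` and renormalized; reads are drawn
    multinomially at a depth drawn around the condition's mean depth.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 3]))
    roster = assign_taxa(config).set_index("taxon_id")
    cols = {}
    for sample in truth.true_abundance.columns:
        col = truth.true_abundance[sample].to_numpy()
        rel = col / col.sum()
        noisy = rel * _lognormal_factors(rng, config.technical_cv, rel.size)
        noisy = noisy / noisy.sum()
        condition = truth.metadata.loc[sample, "condition"]
        depth = _draw_depth(rng, config.read_depth_mean[condition], config.read_depth_cv)
        cols[sample] = rng.multinomial(depth, noisy)
    counts = pd.DataFrame(cols, index=truth.true_abundance.index)
    return CountTable(counts=counts, taxonomy=roster["taxonomy"])


def simulate_cell_counts(
    truth: GroundTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Flow-cytometry measurement: true density x mean-1 log-normal noise."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 4]))
    noise = _lognormal_factors(rng, config.density_cv, len(truth.true_density))
    measured = truth.true_density * noise
    measured.name = "total_cells_per_ml"
    return measured


def generate_experiment(config: SyntheticConfig) -> Experiment:
    """Full simulated experiment: counts, metadata, measured densities, truth.

    Deterministic under ``config.rng_seed``; sample ids encode donor and
    condition as ``D<k>_<condition>``.
    """
    baseline = generate_baseline(config)
    truth = apply_effects(baseline, config)
    counts = simulate_sequencing(truth, config)
    densities = simulate_cell_counts(truth, config)
    return Experiment(counts, truth.metadata, densities, truth)


# Invented but realistic condition means for ex vivo fermentation endpoints
# (concentrations in mM, gas as arbitrary pressure units); the dextran/inulin
# contrasts mirror the emulated study: ~25% more propionate and ~31% less gas
# for dextran than inulin, valerate depressed by inulin, bCFA lowered and pH
# dropped by both treatments.
_FERMENTATION_MEANS = {
    "acetate": {"NSC": 15.0, "inulin": 40.0, "dextran": 35.0},
    "propionate": {"NSC": 8.0, "inulin": 16.0, "dextran": 20.0},
    "butyrate": {"NSC": 5.0, "inulin": 10.0, "dextran": 12.0},
    "valerate": {"NSC": 1.5, "inulin": 0.8, "dextran": 1.5},
    "isobutyrate": {"NSC": 0.6, "inulin": 0.3, "dextran": 0.3},
    "isocaproate": {"NSC": 0.1, "inulin": 0.05, "dextran": 0.05},
    "isovalerate": {"NSC": 0.8, "inulin": 0.4, "dextran": 0.4},
    "gas_pressure": {"NSC": 40.0, "inulin": 100.0, "dextran": 69.0},
    "pH": {"NSC": 6.8, "inulin": 5.9, "dextran": 6.0},
}


def simulate_fermentation(
    metadata: pd.DataFrame,
    rng: np.random.Generator | int = 0,
    noise_cv: float = 0.08,
    means: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Condition-shifted Gaussian metabolite table for the given samples.

    No fermentation kinetics are modelled; each metric is Gaussian around a
    per-condition mean with CV ``noise_cv``, truncated at zero (pH at its
    physical range).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(np.random.SeedSequence([int(rng), 5]))
    means = means or _FERMENTATION_MEANS
    rows = {}
    for sample, row in metadata.iterrows():
        cond = row["condition"]
        vals = {}
        for metric, by_cond in means.items():
            m = by_cond.get(cond)
            if m is None:
                raise ValueError(f"no fermentation mean for condition {cond!r}")
            v = rng.normal(m, noise_cv * m)
            vals[metric] = float(np.clip(v, 1e-6, 14.0 if metric == "pH" else np.inf))
        rows[sample] = vals
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "sample_id"
    return table
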