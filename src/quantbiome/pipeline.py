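"""End-to-end orchestration: simulate or load, quantify, score, test, report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .differential import DEFAULT_FDR, DEFAULT_MIN_DETECTED, effect_table
from .diversity import (
    DEFAULT_CMS_THRESHOLD,
    alpha_diversity_table,
    cms_scores,
    cms_summary,
)
from .fermentation import metabolite_effects
from .io import (
    read_count_table,
    read_density_table,
    read_metadata,
    require_density_coverage,
    write_count_table,
    write_density_table,
    write_effect_table,
    write_metadata,
)
from .quantify import impute_below_lod, quantitative_profile, select_top_n
from .synthetic import SyntheticConfig, generate_experiment, simulate_fermentation

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("quantbiome")


@dataclass
class RunConfig:
    """One pipeline run: either file inputs or a synthetic configuration."""

    counts_path: Path | None = None
    densities_path: Path | None = None
    metadata_path: Path | None = None
    metabolites_path: Path | None = None
    synthetic: SyntheticConfig | None = None
    control: str = "NSC"
    threshold: float = DEFAULT_CMS_THRESHOLD
    top_n: int = 100
    fdr: float = DEFAULT_FDR
    min_detected: int = DEFAULT_MIN_DETECTED
    impute_policy: str = "overall"
    outdir: Path = field(default_factory=lambda: Path("quantbiome_out"))

    def __post_init__(self) -> None:
        has_files = self.counts_path is not None
        if has_files == (self.synthetic is not None):
            raise ValueError("provide exactly one of input paths or a synthetic config")
        if has_files and (self.densities_path is None or self.metadata_path is None):
            raise ValueError("file input needs counts, densities and metadata paths")
        if not (0 < self.threshold < 10):
            raise ValueError("threshold out of range")
        if not (0 < self.fdr <= 1):
            raise ValueError("fdr out of range")
        if self.top_n < 1 or self.min_detected < 1:
            raise ValueError("top_n and min_detected must be >= 1")


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage in order and write all tables under ``config.outdir``.

    Stages: (synthetic generation) -> quantitative profiling -> LOD
    imputation -> top-N restriction -> alpha diversity -> CMS -> paired
    differential testing -> metabolite summaries -> plain-text run report.
    Idempotent for a fixed configuration (and seed, when synthetic).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: list[str] = [f"quantbiome v{__version__}"]

    metabolites = None
    if config.synthetic is not None:
        cfg = config.synthetic
        counts, metadata, densities, _truth = generate_experiment(cfg)
        metabolites = simulate_fermentation(metadata, rng=cfg.rng_seed)
        report.append(f"stage simulate: seed={cfg.rng_seed}, "
                      f"{len(metadata)} samples, {cfg.n_taxa} taxa")
        write_count_table(counts, outdir / "counts.tsv")
        write_metadata(metadata, outdir / "metadata.tsv")
        write_density_table(densities, outdir / "densities.tsv")
    else:
        counts = _stage("read counts", read_count_table, config.counts_path)
        metadata = _stage("read metadata", read_metadata, config.metadata_path)
        densities = _stage("read densities", read_density_table, config.densities_path)
        if config.metabolites_path is not None:
            metabolites = pd.read_csv(
                config.metabolites_path, sep="\t", index_col="sample_id"
            )
        require_density_coverage(densities, counts.sample_ids)

    if config.control not in set(metadata["condition"]):
        raise ValueError(
            f"stage cms: control condition {config.control!r} missing from metadata"
        )

    matrix = quantitative_profile(counts, densities)
    imputed = impute_below_lod(matrix, policy=config.impute_policy)
    n_imputed = int(imputed.imputed.to_numpy().sum())
    report.append(
        f"stage quantify: overall LOD = {imputed.overall_lod!r} cells/mL, "
        f"{n_imputed} entries imputed ({config.impute_policy})"
    )

    top = select_top_n(imputed, n=config.top_n)
    report.append(
        f"stage top-n: retained {len(top)} of {len(matrix.taxon_ids)} taxa "
        f"({len(matrix.taxon_ids) - len(top)} dropped)"
    )
    restricted = imputed.subset_taxa(top)

    diversity = alpha_diversity_table(counts.counts)
    scores = cms_scores(
        restricted, metadata, control=config.control, threshold=config.threshold
    )
    summary = cms_summary(scores)
    effects = effect_table(
        restricted,
        metadata,
        control=config.control,
        fdr=config.fdr,
        min_detected=config.min_detected,
        taxonomy=counts.taxonomy,
    )

    abundance_out = imputed.cells_per_ml.copy()
    abundance_out.index.name = "taxon_id"
    abundance_out.to_csv(outdir / "abundance_cells_per_ml.tsv", sep="\t")
    diversity.to_csv(outdir / "diversity.tsv", sep="\t")
    scores.to_csv(outdir / "cms.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "cms_summary.tsv", sep="\t", index=False)
    write_effect_table(effects, outdir / "effects.tsv")

    results = {
        "abundance": imputed.cells_per_ml,
        "diversity": diversity,
        "cms": scores,
        "cms_summary": summary,
        "effects": effects,
    }
    if metabolites is not None:
        met_effects = metabolite_effects(metabolites, metadata, control=config.control)
        metabolites.to_csv(outdir / "metabolites.tsv", sep="\t")
        met_effects.to_csv(outdir / "metabolite_effects.tsv", sep="\t", index=False)
        results["metabolites"] = metabolites
        results["metabolite_effects"] = met_effects
        report.append(f"stage metabolites: {metabolites.shape[1]} metrics tested")

    report.append(
        "parameters: "
        f"control={config.control} threshold={config.threshold} "
        f"top_n={config.top_n} fdr={config.fdr} min_detected={config.min_detected}"
    )
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    for line in report:
        log.info(line)
    return results


def _stage(name, fn, *args):
    try:
        return fn(*args)
    except Exception as exc:
        raise RuntimeError(f"stage {name}: {exc}") from exc
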