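"""Quantitative microbiome profiling (QMP).

Proportional 16S profiles are scaled by flow-cytometry total cell densities to
estimated absolute abundances (cells/mL), assuming one 16S rRNA gene copy per
cell.  Each sample carries an explicit limit of detection (LOD): the abundance
corresponding to a single read,

    LOD_fraction = 1 / total_reads          (as a percentage: 100/total_reads)
    LOD_cells    = density / total_reads

Values below the detection floor are imputed at the overall LOD (the maximum
per-sample LOD of the analysed set) so that downstream log-scale statistics
and abundance ratios stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CountTable, require_density_coverage

__all__ = [
    "AbundanceMatrix",
    "relative_abundances",
    "absolute_abundances",
    "lod_fraction",
    "lod_percent_reported",
    "sample_lod",
    "quantitative_profile",
    "impute_below_lod",
    "select_top_n",
]


@dataclass
class AbundanceMatrix:
    """Estimated absolute abundances with per-sample detection limits.

    Attributes
    ----------
    cells_per_ml:
        taxa x samples DataFrame of estimated absolute abundances.
    lod_cells_per_ml:
        Per-sample LOD (cells/mL) = density / total reads.
    imputed:
        Boolean taxa x samples DataFrame flagging entries replaced by the LOD.
    overall_lod:
        The uniform imputation floor used, if imputation was applied.
    """

    cells_per_ml: pd.DataFrame
    lod_cells_per_ml: pd.Series
    imputed: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    overall_lod: float | None = None

    def __post_init__(self) -> None:
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.cells_per_ml.index, columns=self.cells_per_ml.columns
            )
        if (self.lod_cells_per_ml <= 0).any():
            raise ValueError("per-sample LOD must be positive")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.cells_per_ml.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cells_per_ml.columns)

    def subset_taxa(self, taxa: list[str]) -> "AbundanceMatrix":
        return replace(
            self,
            cells_per_ml=self.cells_per_ml.loc[taxa],
            imputed=self.imputed.loc[taxa],
        )


def relative_abundances(counts: CountTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample proportions; every column sums to 1."""
    mat = counts.counts if isinstance(counts, CountTable) else counts
    totals = mat.sum(axis=0)
    empty = totals.index[totals <= 0].tolist()
    if empty:
        raise ValueError(f"samples with zero total reads: {empty}")
    return mat / totals


def absolute_abundances(proportions: pd.DataFrame, densities: pd.Series) -> pd.DataFrame:
    """Scale proportions by total cell density: entry = proportion x density."""
    require_density_coverage(densities, list(proportions.columns))
    return proportions * densities[proportions.columns]


def lod_fraction(total_reads: int | float | np.ndarray) -> float | np.ndarray:
    """Detection limit as a percentage of the community: 100 x 1/total_reads."""
    reads = np.asarray(total_reads, dtype=float)
    if (reads < 1).any():
        raise ValueError("total_reads must be >= 1")
    out = 100.0 / reads
    return float(out) if out.ndim == 0 else out


def _round_half_up(x: float, decimals: int) -> float:
    scale = 10.0**decimals
    return float(np.floor(x * scale + 0.5) / scale)


def lod_percent_reported(total_reads: int | float) -> float:
    """Detection-limit percentage rounded for reporting.

    Stepwise half-up rounding (4 decimal places, then 3) matches the
    convention of the published detection limits: 18,197 reads -> 0.0055%
    -> 0.006%; 32,779 -> 0.003%; 25,621 -> 0.004%.
    """
    return _round_half_up(_round_half_up(lod_fraction(total_reads), 4), 3)


def sample_lod(
    total_reads: int | float | np.ndarray, density: float | np.ndarray
) -> float | np.ndarray:
    """Smallest detectable absolute abundance (cells/mL): density / total_reads."""
    reads = np.asarray(total_reads, dtype=float)
    dens = np.asarray(density, dtype=float)
    if (reads < 1).any():
        raise ValueError("total_reads must be >= 1")
    if (dens <= 0).any():
        raise ValueError("density must be positive")
    out = dens / reads
    return float(out) if out.ndim == 0 else out


def quantitative_profile(counts: CountTable, densities: pd.Series) -> AbundanceMatrix:
    """Full QMP step: counts + densities -> absolute abundances with LODs.

    Column sums of the result equal the measured densities exactly (before
    any imputation).
    """
    props = relative_abundances(counts)
    cells = absolute_abundances(props, densities)
    totals = counts.total_reads()
    lods = pd.Series(
        sample_lod(totals.to_numpy(), densities[totals.index].to_numpy()),
        index=totals.index,
        name="lod_cells_per_ml",
    )
    return AbundanceMatrix(cells_per_ml=cells, lod_cells_per_ml=lods)


def impute_below_lod(matrix: AbundanceMatrix, policy: str = "overall") -> AbundanceMatrix:
    """Replace sub-LOD entries by the detection floor and flag them.

    policy="overall" (default) uses a single uniform floor, the maximum
    per-sample LOD of the analysed set — the most conservative detectable
    level, guaranteeing no imputed value sits below any sample's own floor.
    policy="per-sample" uses each sample's individual LOD instead.
    """
    cells = matrix.cells_per_ml.copy()
    if policy == "overall":
        floor = float(matrix.lod_cells_per_ml.max())
        mask = cells < floor
        cells = cells.mask(mask, floor)
        overall = floor
    elif policy == "per-sample":
        floors = matrix.lod_cells_per_ml[cells.columns]
        mask = cells.lt(floors, axis=1)
        cells = cells.mask(mask, floors, axis=1)
        overall = None
    else:
        raise ValueError(f"unknown imputation policy {policy!r}")
    return AbundanceMatrix(
        cells_per_ml=cells,
        lod_cells_per_ml=matrix.lod_cells_per_ml,
        imputed=matrix.imputed | mask,
        overall_lod=overall,
    )


def select_top_n(matrix: AbundanceMatrix | pd.DataFrame, n: int = 100) -> list[str]:
    """Ids of the n most abundant taxa by mean absolute abundance.

    Ranking is global across all samples of the dataset; ties break toward
    the lexicographically smaller taxon id.  n larger than the taxa count
    returns every taxon.
    """
    cells = matrix.cells_per_ml if isinstance(matrix, AbundanceMatrix) else matrix
    means = cells.mean(axis=1)
    order = means.to_frame("mean").reset_index(names="taxon_id")
    order = order.sort_values(["mean", "taxon_id"], ascending=[False, True])
    return order["taxon_id"].head(n).tolist()
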