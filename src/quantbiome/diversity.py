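"""Alpha-diversity indices and the community modulation score (CMS).

Traditional alpha-diversity indices (observed richness, Chao1, Shannon,
inverse Simpson) are proportional-data statistics and are computed on read
counts.  They are blind to total cell density: a treatment that doubles every
taxon's absolute level leaves them unchanged, and a treatment that raises
biomass raises the detection limit, deflating apparent richness.

The community modulation score addresses this by counting, among the N most
abundant taxa (default 100), those whose *quantitative* abundance (cells/mL)
changed by more than a fold threshold versus the no-substrate control (NSC):

    positive CMS = #{x : treatment_x > NSC_x * (1 + t)}
    negative CMS = -#{x : NSC_x > treatment_x * (1 + t)}
    combined CMS = positive + negative

with t = 0.30 by default — twice the 15% technical standard deviation of
per-taxon quantitative detection between bioreactor replicates, so that a
counted change is ~2 SD away from pure technical noise.  Both inequalities
are strict: a taxon sitting exactly at the 1.3-fold boundary is not counted.
The two criteria are deliberately asymmetric multiplicative tests (x1.3 each
way), not a symmetric log-ratio rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import enspie as _skbio_enspie
from skbio.diversity.alpha import shannon as _skbio_shannon

from .quantify import AbundanceMatrix

__all__ = [
    "TECHNICAL_CV",
    "DEFAULT_CMS_THRESHOLD",
    "CmsResult",
    "observed_richness",
    "chao1",
    "shannon",
    "inverse_simpson",
    "alpha_diversity_table",
    "cms_pair",
    "cms_scores",
    "cms_summary",
]

#: Technical standard deviation of per-taxon quantitative detection between
#: biological replicates of parallel bioreactors (fraction of the mean).
TECHNICAL_CV = 0.15

#: CMS fold-change threshold: twice the technical SD, so a counted change
#: carries ~95% certainty of being real.
DEFAULT_CMS_THRESHOLD = 2 * TECHNICAL_CV


def _as_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


def observed_richness(counts) -> int:
    """Number of taxa with at least one read."""
    return int((_as_counts(counts) >= 1).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    arr = _as_counts(counts).astype(int)
    return float(_skbio_chao1(arr, bias_corrected=True))


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log) over detected taxa."""
    arr = _as_counts(counts)
    if arr.sum() <= 0:
        raise ValueError("shannon undefined for an all-zero sample")
    return float(_skbio_shannon(arr, base=np.e))


def inverse_simpson(counts) -> float:
    """Reciprocal Simpson diversity D = 1 / sum p_i^2."""
    arr = _as_counts(counts)
    if arr.sum() <= 0:
        raise ValueError("inverse Simpson undefined for an all-zero sample")
    return float(_skbio_enspie(arr))


def alpha_diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """All four indices for every sample column of a count table."""
    rows = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy()
        rows[sample] = {
            "observed_otus": observed_richness(col),
            "chao1": chao1(col),
            "shannon": shannon(col),
            "inverse_simpson": inverse_simpson(col),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


@dataclass(frozen=True)
class CmsResult:
    """CMS of one donor's treatment arm against its control arm."""

    positive: int
    negative: int
    n_taxa: int
    threshold: float
    donor: str | None = None
    condition: str | None = None

    @property
    def combined(self) -> int:
        return self.positive + self.negative

    def __post_init__(self) -> None:
        if not (0 <= self.positive <= self.n_taxa):
            raise ValueError("positive CMS out of range")
        if not (-self.n_taxa <= self.negative <= 0):
            raise ValueError("negative CMS out of range")


def cms_pair(
    nsc: pd.Series | np.ndarray,
    treatment: pd.Series | np.ndarray,
    threshold: float = DEFAULT_CMS_THRESHOLD,
    donor: str | None = None,
    condition: str | None = None,
) -> CmsResult:
    """Community modulation score of one treatment arm versus its control.

    Both vectors must cover the same taxon set (the LOD-imputed top-N
    abundances), so that every ratio is finite and comparable.
    """
    if isinstance(nsc, pd.Series) and isinstance(treatment, pd.Series):
        if not nsc.index.equals(treatment.index):
            raise ValueError("control and treatment vectors cover different taxa")
    a = np.asarray(nsc, dtype=float)
    b = np.asarray(treatment, dtype=float)
    if a.shape != b.shape:
        raise ValueError("control and treatment vectors differ in length")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("abundances must be strictly positive (LOD-imputed)")
    factor = 1.0 + threshold
    positive = int((b > a * factor).sum())
    negative = -int((a > b * factor).sum())
    return CmsResult(
        positive=positive,
        negative=negative,
        n_taxa=a.size,
        threshold=threshold,
        donor=donor,
        condition=condition,
    )


def cms_scores(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    control: str = "NSC",
    threshold: float = DEFAULT_CMS_THRESHOLD,
    taxa: list[str] | None = None,
) -> pd.DataFrame:
    """Per donor x treatment CMS over an (imputed, top-N restricted) matrix.

    ``taxa`` optionally restricts scoring to a taxon subset (e.g. the global
    top 100); by default every taxon in the matrix is scored.
    """
    cells = matrix.cells_per_ml if taxa is None else matrix.cells_per_ml.loc[taxa]
    if metadata["condition"].eq(control).sum() == 0:
        raise ValueError(f"control condition {control!r} absent from metadata")
    rows = []
    for donor, group in metadata.groupby("donor", sort=True):
        ctrl_samples = group.index[group["condition"] == control]
        if len(ctrl_samples) != 1:
            raise ValueError(f"donor {donor!r} needs exactly one {control!r} sample")
        ctrl = cells[ctrl_samples[0]]
        for sample_id, row in group[group["condition"] != control].iterrows():
            res = cms_pair(
                ctrl, cells[sample_id], threshold=threshold,
                donor=str(donor), condition=str(row["condition"]),
            )
            rows.append(
                {
                    "donor": res.donor,
                    "condition": res.condition,
                    "positive_cms": res.positive,
                    "negative_cms": res.negative,
                    "combined_cms": res.combined,
                    "n_taxa": res.n_taxa,
                    "threshold": res.threshold,
                }
            )
    return pd.DataFrame(rows)


def cms_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Cross-donor mean and SD of each score, per condition.

    A single donor yields SD 0 by convention.  Means of integer per-donor
    scores are generally non-integers.
    """
    def _sd(x: pd.Series) -> float:
        return float(x.std(ddof=1)) if len(x) > 1 else 0.0

    out = (
        scores.groupby("condition")
        .agg(
            n_donors=("donor", "nunique"),
            mean_positive=("positive_cms", "mean"),
            sd_positive=("positive_cms", _sd),
            mean_negative=("negative_cms", "mean"),
            sd_negative=("negative_cms", _sd),
            mean_combined=("combined_cms", "mean"),
            sd_combined=("combined_cms", _sd),
        )
        .reset_index()
    )
    return out
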