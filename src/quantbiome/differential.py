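"""Paired treatment-vs-control testing across donors, FDR control and the
consistency classification.

Each taxon is tested with a within-donor paired location test on log10
abundances (a two-condition repeated-measures analysis with donor as subject
is algebraically the paired t-test, F = t^2).  P-values are adjusted per
treatment contrast with Benjamini-Hochberg at FDR 0.20.  Taxa that miss
significance are still classed as consistent responders when they are
detected (above LOD in either arm) in at least 4 of 6 donors and move in the
same direction in every donor where detected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import family_from_lineage
from .quantify import AbundanceMatrix

__all__ = [
    "paired_contrast",
    "bh_adjust",
    "consistency_classify",
    "effect_table",
    "family_rollup",
]

DEFAULT_FDR = 0.20
DEFAULT_MIN_DETECTED = 4


def paired_contrast(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    treatment: str,
    control: str = "NSC",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-row paired test of treatment against control across donors.

    ``values`` is rows (taxa or metrics) x samples, strictly positive when
    ``log_transform`` is on (i.e. LOD-imputed abundances).  Testing is on
    log10 values; the reported effect size is the mean over donors of
    log2(treatment/control).  With ``log_transform=False`` (e.g. pH, gas
    pressure) the test runs on raw values and ``mean_diff`` replaces the log
    ratio.

    Returns a DataFrame with columns ``mean_log2_ratio`` (or ``mean_diff``),
    ``p_value``, ``n_pairs`` and ``degenerate``.  Zero-variance difference
    vectors get p = 1 (all-zero differences) or p = 0 with the degenerate
    flag set (constant non-zero shift) instead of a fabricated statistic;
    fewer than 3 complete pairs leaves p undefined (NaN), flagged.
    """
    donors = sorted(metadata["donor"].unique())
    t_cols, c_cols, kept = [], [], []
    for donor in donors:
        grp = metadata[metadata["donor"] == donor]
        t = grp.index[grp["condition"] == treatment]
        c = grp.index[grp["condition"] == control]
        if len(t) == 1 and len(c) == 1:
            t_cols.append(t[0])
            c_cols.append(c[0])
            kept.append(donor)
    if not kept:
        raise ValueError(f"no donor has both {treatment!r} and {control!r} arms")

    tv = values[t_cols].to_numpy(dtype=float)
    cv = values[c_cols].to_numpy(dtype=float)
    if log_transform:
        if (tv <= 0).any() or (cv <= 0).any():
            raise ValueError("log-scale testing requires strictly positive values")
        lt, lc = np.log10(tv), np.log10(cv)
        effect = np.mean(np.log2(tv) - np.log2(cv), axis=1)
        effect_name = "mean_log2_ratio"
    else:
        lt, lc = tv, cv
        effect = (tv - cv).mean(axis=1)
        effect_name = "mean_diff"
    diffs = lt - lc

    n = diffs.shape[1]
    p = np.full(diffs.shape[0], np.nan)
    degenerate = np.zeros(diffs.shape[0], dtype=bool)
    if n >= 3:
        sd = diffs.std(axis=1, ddof=1)
        mean = diffs.mean(axis=1)
        regular = sd > 0
        if regular.any():
            res = stats.ttest_rel(lt[regular].T, lc[regular].T, axis=0)
            p[regular] = res.pvalue
        zero_shift = (~regular) & (mean == 0)
        const_shift = (~regular) & (mean != 0)
        p[zero_shift] = 1.0  # no change anywhere: no evidence against the null
        p[const_shift] = 0.0  # identical non-zero shift in every donor
        degenerate = ~regular
    else:
        degenerate[:] = True

    return pd.DataFrame(
        {effect_name: effect, "p_value": p, "n_pairs": n, "degenerate": degenerate},
        index=values.index,
    )


def bh_adjust(p_values, fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """Benjamini-Hochberg step-up q-values with a significance flag at ``fdr``.

    NaN p-values (degenerate tests) pass through as NaN and are excluded
    from the correction count.
    """
    p = pd.Series(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = pd.Series(np.nan, index=p.index)
    ok = p.notna()
    if ok.any():
        _, qv, _, _ = multipletests(p[ok].to_numpy(), method="fdr_bh")
        q[ok] = qv
    return pd.DataFrame({"p_value": p, "q_value": q, "significant": q <= fdr})


def consistency_classify(
    log2_ratios,
    detected,
    min_detected: int = DEFAULT_MIN_DETECTED,
) -> str:
    """Consistency class of a non-significant taxon.

    ``detected`` flags the donors where the taxon was above the LOD in either
    arm.  The taxon is ``consistent_up`` when it is detected in at least
    ``min_detected`` donors and its ratio is positive in *every* detected
    donor (``consistent_down`` symmetric); any disagreement, or too few
    detections, yields ``none``.
    """
    ratios = np.asarray(log2_ratios, dtype=float)
    det = np.asarray(detected, dtype=bool)
    if ratios.shape != det.shape:
        raise ValueError("ratios and detection flags differ in length")
    r = ratios[det]
    if det.sum() < min_detected or r.size == 0:
        return "none"
    if (r > 0).all():
        return "consistent_up"
    if (r < 0).all():
        return "consistent_down"
    return "none"


def _detection_by_donor(
    matrix: AbundanceMatrix, metadata: pd.DataFrame, treatment: str, control: str
) -> pd.DataFrame:
    """Taxa x donors: detected (non-imputed) in either arm of that donor."""
    cols = {}
    for donor, grp in metadata.groupby("donor", sort=True):
        arm_samples = grp.index[grp["condition"].isin([treatment, control])]
        cols[donor] = ~matrix.imputed[arm_samples].all(axis=1)
    return pd.DataFrame(cols)


def effect_table(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    treatments: list[str] | None = None,
    control: str = "NSC",
    fdr: float = DEFAULT_FDR,
    min_detected: int = DEFAULT_MIN_DETECTED,
    taxonomy: pd.Series | None = None,
) -> pd.DataFrame:
    """Full per-taxon effect table over one or more treatment contrasts.

    The matrix must be LOD-imputed (and typically top-N restricted).  BH
    correction is applied within each treatment contrast.  Every taxon gets
    exactly one class per contrast: significant_up/down when q <= fdr,
    else the consistency rule, else none.
    """
    if treatments is None:
        treatments = sorted(set(metadata["condition"]) - {control})
    frames = []
    for treatment in treatments:
        contrast = paired_contrast(matrix.cells_per_ml, metadata, treatment, control)
        adj = bh_adjust(contrast["p_value"], fdr=fdr)
        detected = _detection_by_donor(matrix, metadata, treatment, control)

        # per-donor log2 ratios for the consistency rule
        donors = list(detected.columns)
        ratio_cols = {}
        for donor in donors:
            grp = metadata[metadata["donor"] == donor]
            t = grp.index[grp["condition"] == treatment]
            c = grp.index[grp["condition"] == control]
            if len(t) == 1 and len(c) == 1:
                ratio_cols[donor] = np.log2(
                    matrix.cells_per_ml[t[0]] / matrix.cells_per_ml[c[0]]
                )
        ratios = pd.DataFrame(ratio_cols)

        classes = []
        for taxon in matrix.cells_per_ml.index:
            if bool(adj.loc[taxon, "significant"]):
                direction = "up" if contrast.loc[taxon, "mean_log2_ratio"] > 0 else "down"
                classes.append(f"significant_{direction}")
            else:
                classes.append(
                    consistency_classify(
                        ratios.loc[taxon, donors],
                        detected.loc[taxon, donors],
                        min_detected=min_detected,
                    )
                )
        fam = (
            taxonomy.reindex(matrix.cells_per_ml.index).map(family_from_lineage)
            if taxonomy is not None
            else pd.Series("unclassified", index=matrix.cells_per_ml.index)
        )
        frames.append(
            pd.DataFrame(
                {
                    "taxon_id": matrix.cells_per_ml.index,
                    "family": fam.to_numpy(),
                    "condition": treatment,
                    "mean_log2_ratio": contrast["mean_log2_ratio"].to_numpy(),
                    "p_value": adj["p_value"].to_numpy(),
                    "q_value": adj["q_value"].to_numpy(),
                    "class": classes,
                    "n_detected": detected.sum(axis=1).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def family_rollup(
    abundances: pd.DataFrame, taxonomy: pd.Series
) -> pd.DataFrame:
    """Sum taxa into family-level rows; unmapped taxa fall under 'unclassified'.

    Column totals are preserved, so the same paired testing machinery applies
    unchanged at family level.
    """
    families = taxonomy.reindex(abundances.index).map(family_from_lineage)
    rolled = abundances.groupby(families.to_numpy()).sum()
    rolled.index.name = "family"
    return rolled
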