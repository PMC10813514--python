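"""Derived summaries of fermentation endpoints (SCFA, bCFA, gas, pH).

Totals and ratios are exact arithmetic on the measured concentrations;
treatment-vs-treatment percent differences are computed on donor-paired
condition means; paired significance reuses the same machinery as the
taxon-level contrasts (without the log transform, since pH and pressure are
not log-scale quantities).
"""

from __future__ import annotations

import pandas as pd

from .differential import paired_contrast

__all__ = [
    "SCFA_FIELDS",
    "BCFA_FIELDS",
    "total_scfa",
    "bcfa_sum",
    "propionate_acetate_ratio",
    "percent_difference",
    "metabolite_effects",
]

SCFA_FIELDS = ["acetate", "propionate", "butyrate", "valerate"]
BCFA_FIELDS = ["isobutyrate", "isocaproate", "isovalerate"]


def _require(table: pd.DataFrame | pd.Series, fields: list[str]) -> None:
    cols = table.index if isinstance(table, pd.Series) else table.columns
    missing = [f for f in fields if f not in cols]
    if missing:
        raise ValueError(f"missing metabolite fields: {missing}")


def total_scfa(table: pd.DataFrame | pd.Series):
    """Total short-chain fatty acids: acetate + propionate + butyrate + valerate."""
    _require(table, SCFA_FIELDS)
    return table[SCFA_FIELDS].sum() if isinstance(table, pd.Series) else table[
        SCFA_FIELDS
    ].sum(axis=1)


def bcfa_sum(table: pd.DataFrame | pd.Series):
    """Branched-chain fatty acids: isobutyrate + isocaproate + isovalerate."""
    _require(table, BCFA_FIELDS)
    return table[BCFA_FIELDS].sum() if isinstance(table, pd.Series) else table[
        BCFA_FIELDS
    ].sum(axis=1)


def propionate_acetate_ratio(table: pd.DataFrame | pd.Series):
    """Propionate:acetate ratio; higher values favour propiogenic fermentation."""
    _require(table, ["acetate", "propionate"])
    acetate = table["acetate"]
    if (acetate <= 0) if isinstance(table, pd.Series) else (acetate <= 0).any():
        raise ValueError("acetate must be positive for the ratio")
    return table["propionate"] / acetate


def percent_difference(
    values: pd.Series,
    metadata: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    method: str = "ratio_of_means",
) -> float:
    """Signed percent difference of a metric between two conditions.

    Donors present in both conditions are paired; the default reports
    100 x (mean_a - mean_b) / mean_b over those paired donor values
    (ratio of cross-donor means, robust to small denominators).
    ``method="mean_of_ratios"`` averages per-donor percent changes instead.
    """
    meta = metadata.loc[values.index.intersection(metadata.index)]
    a = values[meta.index[meta["condition"] == condition_a]]
    b = values[meta.index[meta["condition"] == condition_b]]
    da = meta.loc[a.index, "donor"]
    db = meta.loc[b.index, "donor"]
    paired = sorted(set(da) & set(db))
    if not paired:
        raise ValueError(
            f"no donors have both {condition_a!r} and {condition_b!r} measurements"
        )
    a_by = a.groupby(da.to_numpy()).mean()[paired]
    b_by = b.groupby(db.to_numpy()).mean()[paired]
    if method == "ratio_of_means":
        mb = b_by.mean()
        if mb == 0:
            raise ValueError("reference condition mean is zero")
        return float(100.0 * (a_by.mean() - mb) / mb)
    if method == "mean_of_ratios":
        if (b_by == 0).any():
            raise ValueError("reference value zero for some donor")
        return float((100.0 * (a_by - b_by) / b_by).mean())
    raise ValueError(f"unknown method {method!r}")


def metabolite_effects(
    table: pd.DataFrame,
    metadata: pd.DataFrame,
    control: str = "NSC",
    treatments: list[str] | None = None,
) -> pd.DataFrame:
    """Paired treatment-vs-control tests for every metabolite column.

    Returns one row per metric x treatment with the mean paired difference
    and its p-value.
    """
    if treatments is None:
        treatments = sorted(set(metadata["condition"]) - {control})
    frames = []
    for treatment in treatments:
        res = paired_contrast(
            table.T, metadata, treatment, control, log_transform=False
        )
        res = res.rename_axis("metric").reset_index()
        res.insert(1, "condition", treatment)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
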