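"""Tabular I/O for the pipeline: count tables, metadata, densities, effect tables.

All interchange files are plain TSV (tab delimiter, UTF-8, "." decimal).  The
count-table layout is taxa x samples with the literal header cell ``taxon_id``
in the top-left corner.  Every reader validates its invariants and raises
:class:`TableFormatError` naming the offending row/column where possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TableFormatError",
    "CountTable",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_density_table",
    "write_density_table",
    "read_effect_table",
    "write_effect_table",
    "family_from_lineage",
    "require_density_coverage",
]

TAXON_COLUMN = "taxon_id"


class TableFormatError(ValueError):
    """A table violated the expected layout or an invariant."""


@dataclass
class CountTable:
    """Sequencing read counts, taxa x samples, with optional taxonomy.

    Parameters
    ----------
    counts:
        Integer DataFrame indexed by taxon id with sample ids as columns.
    taxonomy:
        Optional mapping taxon id -> semicolon-delimited lineage string.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate taxon ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample ids: {dups}")
        values = counts.to_numpy()
        if np.isnan(values.astype(float)).any():
            r, c = np.argwhere(np.isnan(values.astype(float)))[0]
            raise TableFormatError(
                f"missing count at taxon {counts.index[r]!r}, sample {counts.columns[c]!r}"
            )
        if (values.astype(float) % 1 != 0).any():
            r, c = np.argwhere(values.astype(float) % 1 != 0)[0]
            raise TableFormatError(
                f"non-integer count at taxon {counts.index[r]!r}, sample {counts.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise TableFormatError(
                f"negative count at taxon {counts.index[r]!r}, sample {counts.columns[c]!r}"
            )
        self.counts = counts.astype(np.int64)
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def total_reads(self) -> pd.Series:
        """Realized sequencing depth per sample."""
        return self.counts.sum(axis=0)


def read_count_table(path: str | Path) -> CountTable:
    """Read a taxa x samples TSV of read counts.

    First column holds taxon ids (header cell ``taxon_id``); an optional final
    column named ``taxonomy`` carries lineage strings.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dups = [name for i, name in enumerate(header[1:]) if name in header[1 : i + 1]]
    if dups:
        raise TableFormatError(f"{path.name}: duplicated sample header {sorted(set(dups))}")
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != TAXON_COLUMN:
        raise TableFormatError(
            f"{path.name}: first header cell must be {TAXON_COLUMN!r}, got {raw.columns[0]!r}"
        )
    raw = raw.set_index(TAXON_COLUMN)
    taxonomy = None
    if "taxonomy" in raw.columns:
        taxonomy = raw.pop("taxonomy")
        taxonomy.name = "taxonomy"
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise TableFormatError(f"{path.name}: duplicated sample header {dups}")
    for col in raw.columns:
        bad = raw.index[raw[col].str.strip() == ""]
        if len(bad):
            raise TableFormatError(
                f"{path.name}: empty/ragged cell at taxon {bad[0]!r}, sample {col!r}"
            )
    try:
        counts = raw.astype(float)
    except ValueError as exc:
        raise TableFormatError(f"{path.name}: non-numeric count ({exc})") from exc
    return CountTable(counts=counts, taxonomy=taxonomy)


def write_count_table(table: CountTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.index.name = TAXON_COLUMN
    if table.taxonomy is not None:
        out = out.assign(taxonomy=table.taxonomy)
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata: columns sample_id, donor, condition."""
    path = Path(path)
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "donor", "condition"}
    missing = required - set(meta.columns)
    if missing:
        raise TableFormatError(f"{path.name}: missing metadata columns {sorted(missing)}")
    return validate_metadata(meta.set_index("sample_id"))


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate sample ids in metadata: {dups}")
    pairs = meta[["donor", "condition"]]
    if pairs.duplicated().any():
        dup = pairs[pairs.duplicated()].iloc[0]
        raise TableFormatError(
            f"duplicate (donor, condition) pair in metadata: ({dup['donor']}, {dup['condition']})"
        )
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_density_table(path: str | Path) -> pd.Series:
    """Read per-sample total cell densities (cells/mL) as a Series."""
    path = Path(path)
    dens = pd.read_csv(path, sep="\t")
    if "sample_id" not in dens.columns or "total_cells_per_ml" not in dens.columns:
        raise TableFormatError(
            f"{path.name}: expected columns sample_id, total_cells_per_ml"
        )
    series = dens.set_index("sample_id")["total_cells_per_ml"].astype(float)
    if series.index.has_duplicates:
        dups = series.index[series.index.duplicated()].unique().tolist()
        raise TableFormatError(f"{path.name}: duplicate sample ids {dups}")
    nonpos = series.index[series <= 0].tolist()
    if nonpos:
        raise TableFormatError(f"{path.name}: non-positive density for samples {nonpos}")
    return series


def write_density_table(densities: pd.Series, path: str | Path) -> None:
    out = densities.rename("total_cells_per_ml").to_frame()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def require_density_coverage(densities: pd.Series, sample_ids: list[str]) -> None:
    """Fail loudly if any sample lacks a measured density."""
    missing = [s for s in sample_ids if s not in densities.index]
    if missing:
        raise TableFormatError(f"density table missing samples: {missing}")


EFFECT_COLUMNS = [
    "taxon_id",
    "family",
    "condition",
    "mean_log2_ratio",
    "p_value",
    "q_value",
    "class",
    "n_detected",
]


def write_effect_table(effects: pd.DataFrame, path: str | Path) -> None:
    """Write a per-taxon effect table (long format, one row per taxon x treatment)."""
    out = effects.reset_index() if effects.index.name == "taxon_id" else effects.copy()
    missing = [c for c in EFFECT_COLUMNS if c not in out.columns]
    if missing:
        raise TableFormatError(f"effect table missing columns {missing}")
    out[EFFECT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_effect_table(path: str | Path) -> pd.DataFrame:
    eff = pd.read_csv(path, sep="\t")
    missing = [c for c in EFFECT_COLUMNS if c not in eff.columns]
    if missing:
        raise TableFormatError(f"{Path(path).name}: missing columns {missing}")
    return eff


def family_from_lineage(lineage: str | None) -> str:
    """Extract the family rank from a semicolon-delimited lineage string.

    Takes the rank prefixed ``f__`` if present, else the 5th field; anything
    unresolvable maps to ``"unclassified"``.
    """
    if lineage is None or not isinstance(lineage, str) or not lineage.strip():
        return "unclassified"
    fields = [f.strip() for f in lineage.split(";")]
    for f in fields:
        if f.startswith("f__"):
            name = f[3:].strip()
            return name if name else "unclassified"
    if len(fields) >= 5 and fields[4]:
        return fields[4]
    return "unclassified"
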