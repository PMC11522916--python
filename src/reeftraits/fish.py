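"""Reef-fish survey ingestion and abundance standardisation.

Belt-transect underwater visual censuses count fish along a tape of
known length and width; because transect dimensions changed between
survey years, abundances are standardised to individuals per 60 m²
before any comparison.  Fish are partitioned into coral dwellers (CD)
and non-coral dwellers (NCD) from a literature-derived lookup, and into
four ordered body-length classes.  Size classes are an ordered
categorical axis; they are never converted to midpoint lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import pandas as pd

__all__ = [
    "SIZE_CLASSES",
    "FishRecord",
    "read_fish",
    "write_fish",
    "read_cd_lookup",
    "standardize_abundance",
    "partition_cd_ncd",
]

#: Body-length classes, ordered smallest to largest (cm).
SIZE_CLASSES: tuple[str, ...] = ("<5", "5-10", "10-20", ">20")

_SIZE_ALIASES = {
    "<5": "<5",
    "<5cm": "<5",
    "5-10": "5-10",
    "5–10": "5-10",
    "10-20": "10-20",
    "10–20": "10-20",
    ">20": ">20",
    ">20cm": ">20",
}


@dataclass(frozen=True)
class FishRecord:
    """One visual-census observation of a fish taxon in a size class."""

    site_id: str
    year: int
    taxon: str
    count: int
    size_class: str
    transect_length: float
    belt_width: float = 2.0

    def __post_init__(self) -> None:
        if self.count < 0 or int(self.count) != self.count:
            raise ValueError(f"count must be a non-negative integer, got {self.count}")
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(
                f"size class {self.size_class!r} not in {SIZE_CLASSES}"
            )
        if self.transect_length <= 0 or self.belt_width <= 0:
            raise ValueError("transect dimensions must be positive")

    @property
    def area(self) -> float:
        return self.transect_length * self.belt_width


_FISH_COLUMNS = (
    "site",
    "year",
    "taxon",
    "count",
    "size_class",
    "transect_length_m",
    "belt_width_m",
)


def read_fish(path: str | Path, sep: str | None = None) -> list[FishRecord]:
    """Read one-row-per-observation fish census data."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in _FISH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for idx, row in df.iterrows():
        size = _SIZE_ALIASES.get(str(row["size_class"]).strip())
        if size is None:
            raise ValueError(
                f"{path}, line {idx + 2}: unknown size class {row['size_class']!r}"
            )
        records.append(
            FishRecord(
                str(row["site"]).strip(),
                int(row["year"]),
                str(row["taxon"]).strip(),
                int(row["count"]),
                size,
                float(row["transect_length_m"]),
                float(row["belt_width_m"]),
            )
        )
    return records


def write_fish(records: Iterable[FishRecord], path: str | Path) -> None:
    rows = [
        {
            "site": r.site_id,
            "year": r.year,
            "taxon": r.taxon,
            "count": r.count,
            "size_class": r.size_class,
            "transect_length_m": r.transect_length,
            "belt_width_m": r.belt_width,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_FISH_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_cd_lookup(path: str | Path) -> pd.Series:
    """Read a coral-dweller lookup TSV with columns ``taxon, cd_flag``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"taxon", "cd_flag"}.issubset(df.columns):
        raise ValueError(f"{path}: lookup needs columns taxon, cd_flag")
    flags = df["cd_flag"].astype(str).str.strip().str.lower()
    return pd.Series(
        flags.isin({"1", "true", "yes", "cd"}).to_numpy(),
        index=df["taxon"].astype(str).str.strip(),
        name="cd_flag",
    )


def standardize_abundance(
    records: Sequence[FishRecord],
    by: str = "taxon",
) -> pd.DataFrame:
    """Abundance per 60 m² per (site, year), by taxon or by size class.

    Each record contributes ``count / (length x width) x 60``.  With
    ``by='taxon'`` columns are taxa (size classes summed); with
    ``by='taxon-size'`` columns are (taxon, size_class) pairs.
    """
    if not records:
        raise ValueError("no fish records given")
    if by not in {"taxon", "taxon-size"}:
        raise ValueError(f"unknown grouping {by!r}")
    rows = []
    for r in records:
        rows.append(
            {
                "site": r.site_id,
                "year": r.year,
                "taxon": r.taxon,
                "size_class": r.size_class,
                "abundance": r.count / r.area * 60.0,
            }
        )
    df = pd.DataFrame(rows)
    cols = ["taxon"] if by == "taxon" else ["taxon", "size_class"]
    table = df.pivot_table(
        index=["site", "year"],
        columns=cols,
        values="abundance",
        aggfunc="sum",
        fill_value=0.0,
    )
    return table.sort_index()


def partition_cd_ncd(
    table: pd.DataFrame,
    lookup: pd.Series,
    mode: str = "strict",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an abundance table into coral-dweller and non-coral-dweller parts.

    Taxa are matched in the lookup at species level, then at genus level
    (first word of the name).  In ``strict`` mode an unmatched taxon is an
    error listing all offenders; in ``lenient`` mode it defaults to NCD
    with a warning.  The partition is exhaustive and disjoint, so CD and
    NCD totals sum to the grand total exactly.
    """
    if mode not in {"strict", "lenient"}:
        raise ValueError(f"unknown mode {mode!r}")
    genus_flags: dict[str, bool] = {}
    for taxon, flag in lookup.items():
        genus_flags.setdefault(str(taxon).split()[0], bool(flag))

    def taxon_of(col) -> str:
        return col[0] if isinstance(col, tuple) else col

    flags = {}
    unmatched = []
    for col in table.columns:
        taxon = str(taxon_of(col))
        if taxon in lookup.index:
            flags[col] = bool(lookup[taxon])
        elif taxon.split()[0] in genus_flags:
            flags[col] = genus_flags[taxon.split()[0]]
        else:
            unmatched.append(taxon)
            flags[col] = False
    if unmatched:
        if mode == "strict":
            raise KeyError(f"taxa missing from the CD lookup: {sorted(set(unmatched))}")
        warnings.warn(
            f"taxa missing from the CD lookup treated as NCD: {sorted(set(unmatched))}"
        )
    cd_cols = [c for c in table.columns if flags[c]]
    ncd_cols = [c for c in table.columns if not flags[c]]
    return table[cd_cols], table[ncd_cols]
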