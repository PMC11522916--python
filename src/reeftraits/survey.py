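"""Benthic survey data model and line-intercept cover computation.

The Line Intercept Transect (LIT) method lays a tape along the reef and
records, for every stretch of tape, which benthos or substrate category
lies beneath it.  Cover of a category is the total intercepted length
divided by the total tape length.  Transects of unequal length (a single
50-m tape versus six 10-m replicates) are therefore pooled by length
weighting: cover is a ratio of summed lengths, so pooling the lengths is
the estimator consistent with the definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: The twelve benthos / substrate categories recorded on the field sheets.
BENTHIC_CATEGORIES: tuple[str, ...] = (
    "rock",
    "bare reef",
    "reef-building coral",
    "CCA",
    "sand",
    "soft coral",
    "zoantharian",
    "corallimorpharian",
    "sponge",
    "sea anemone",
    "macroalgae",
    "other",
)

#: Category whose segments carry a coral taxon label.
CORAL_CATEGORY = "reef-building coral"

#: Pseudo-category for tape not assigned to any of the twelve categories.
UNCLASSIFIED = "unclassified"

#: Built-in label normalisation applied before any user dialect map.
DEFAULT_DIALECT: dict[str, str] = {
    "coral": CORAL_CATEGORY,
    "hard coral": CORAL_CATEGORY,
    "reef building coral": CORAL_CATEGORY,
    "crustose coralline algae": "CCA",
    "crude coralline algae": "CCA",
    "cca": "CCA",
    "dead coral": "bare reef",
    "soft corals": "soft coral",
    "sea anemones": "sea anemone",
    "sponges": "sponge",
    "ma": "macroalgae",
    "others": "other",
}

_LEN_TOL = 1e-9


class SurveyParseError(ValueError):
    """Raised when a survey file cannot be parsed or fails validation."""


@dataclass(frozen=True)
class Segment:
    """One intercept: a stretch of tape under a single category."""

    category: str
    taxon: str | None
    length: float

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError(f"negative intercept length {self.length}")
        if self.category == CORAL_CATEGORY and not self.taxon:
            raise ValueError("coral segment requires a taxon label")
        if self.category != CORAL_CATEGORY and self.taxon:
            raise ValueError(
                f"taxon {self.taxon!r} given for non-coral category {self.category!r}"
            )


@dataclass
class TransectRecord:
    """One benthic transect: identity, tape length and its intercepts."""

    site_id: str
    year: int
    protected: bool
    transect_id: str
    transect_length: float
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.transect_length <= 0:
            raise ValueError("transect_length must be positive")
        total = sum(s.length for s in self.segments)
        if total > self.transect_length + _LEN_TOL:
            raise ValueError(
                f"transect {self.transect_id} at {self.site_id}/{self.year}: "
                f"intercepts sum to {total:.4f} m on a "
                f"{self.transect_length:.4f} m tape"
            )

    @property
    def classified_length(self) -> float:
        return sum(s.length for s in self.segments)


def normalize_category(label: str, dialect: Mapping[str, str] | None = None) -> str:
    """Map a field-sheet label onto a canonical category name.

    The user ``dialect`` map takes precedence over the built-in one; the
    lookup is case-insensitive on the raw label.
    """
    raw = label.strip()
    if dialect:
        lowered = {k.lower(): v for k, v in dialect.items()}
        if raw.lower() in lowered:
            return lowered[raw.lower()]
    if raw in BENTHIC_CATEGORIES:
        return raw
    if raw.lower() in DEFAULT_DIALECT:
        return DEFAULT_DIALECT[raw.lower()]
    low = raw.lower()
    if low in BENTHIC_CATEGORIES:
        return low
    raise SurveyParseError(f"unknown benthic category {label!r}")


_REQUIRED_COLUMNS = (
    "site",
    "year",
    "protected",
    "transect_id",
    "transect_length_m",
    "category",
    "taxon",
    "intercept_length_m",
)


def read_transects(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[TransectRecord]:
    """Read one-row-per-intercept survey data into validated records.

    The file is delimited text with the columns ``site, year, protected,
    transect_id, transect_length_m, category, taxon, intercept_length_m``;
    the delimiter is inferred from the extension unless ``sep`` is given.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyParseError(f"{path}: missing required columns {missing}")

    records: dict[tuple, TransectRecord] = {}
    segments: dict[tuple, list[Segment]] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header on line 1
        try:
            site = str(row["site"]).strip()
            year = int(row["year"])
            protected = _parse_bool(row["protected"])
            tid = str(row["transect_id"]).strip()
            tlen = float(row["transect_length_m"])
            category = normalize_category(str(row["category"]), dialect)
            taxon = row["taxon"]
            taxon = None if pd.isna(taxon) or str(taxon).strip() == "" else str(taxon).strip()
            seg = Segment(category, taxon, float(row["intercept_length_m"]))
        except (ValueError, TypeError) as exc:
            raise SurveyParseError(f"{path}, line {line}: {exc}") from exc
        key = (site, year, tid)
        if key not in records:
            records[key] = TransectRecord(site, year, protected, tid, tlen, [])
        elif abs(records[key].transect_length - tlen) > _LEN_TOL:
            raise SurveyParseError(
                f"{path}, line {line}: transect {tid} has inconsistent lengths"
            )
        segments.setdefault(key, []).append(seg)

    out = []
    for key, rec in records.items():
        # re-validate the intercept-sum invariant with all segments attached
        try:
            out.append(
                TransectRecord(
                    rec.site_id,
                    rec.year,
                    rec.protected,
                    rec.transect_id,
                    rec.transect_length,
                    segments[key],
                )
            )
        except ValueError as exc:
            raise SurveyParseError(f"{path}: {exc}") from exc
    return out


def _parse_bool(value) -> bool:
    text = str(value).strip().lower()
    if text in {"1", "true", "yes", "y"}:
        return True
    if text in {"0", "false", "no", "n"}:
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def write_transects(records: Iterable[TransectRecord], path: str | Path) -> None:
    """Write records back to the canonical one-row-per-intercept TSV."""
    rows = []
    for rec in records:
        for seg in rec.segments:
            rows.append(
                {
                    "site": rec.site_id,
                    "year": rec.year,
                    "protected": rec.protected,
                    "transect_id": rec.transect_id,
                    "transect_length_m": rec.transect_length,
                    "category": seg.category,
                    "taxon": seg.taxon or "",
                    "intercept_length_m": seg.length,
                }
            )
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def _group_key(rec: TransectRecord, group_by: Sequence[str]) -> tuple:
    fields = {"site": rec.site_id, "year": rec.year, "protected": rec.protected}
    return tuple(fields[g] for g in group_by)


def compute_cover(
    transects: Sequence[TransectRecord],
    group_by: Sequence[str] = ("site", "year"),
) -> pd.DataFrame:
    """Percent cover of the twelve categories per group of transects.

    Cover of a category within a group is ``100 * (summed intercept length
    of that category) / (summed tape length)``.  Tape that carries no
    intercept is reported under an explicit ``unclassified`` column rather
    than silently renormalised, so every row sums to 100.
    """
    if not transects:
        raise ValueError("no transects given")
    groups: dict[tuple, list[TransectRecord]] = {}
    meta: dict[tuple, dict] = {}
    for rec in transects:
        key = _group_key(rec, group_by)
        groups.setdefault(key, []).append(rec)
        meta.setdefault(key, {"protected": rec.protected})

    columns = list(BENTHIC_CATEGORIES) + [UNCLASSIFIED]
    rows = {}
    for key, recs in sorted(groups.items(), key=lambda kv: tuple(map(str, kv[0]))):
        tape = sum(r.transect_length for r in recs)
        lengths = dict.fromkeys(columns, 0.0)
        for r in recs:
            for seg in r.segments:
                lengths[seg.category] += seg.length
            lengths[UNCLASSIFIED] += r.transect_length - r.classified_length
        rows[key] = {c: 100.0 * lengths[c] / tape for c in columns}

    index = pd.MultiIndex.from_tuples(rows.keys(), names=list(group_by))
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = index
    table.attrs["protected"] = {k: meta[k]["protected"] for k in rows}
    return table


def coral_abundance_matrix(
    transects: Sequence[TransectRecord],
    level: str = "site-year",
) -> pd.DataFrame:
    """Coral taxon percent-cover matrix per assemblage unit.

    ``level='site-year'`` yields one row per (site, year); ``'pooled-year'``
    pools all sites of a year into a single meta-assemblage, equivalent to
    the length-weighted mean of the site rows.
    """
    if level not in {"site-year", "pooled-year"}:
        raise ValueError(f"unknown level {level!r}")
    group_by = ("site", "year") if level == "site-year" else ("year",)

    groups: dict[tuple, list[TransectRecord]] = {}
    prot: dict[tuple, bool] = {}
    for rec in transects:
        key = _group_key(rec, group_by)
        groups.setdefault(key, []).append(rec)
        prot[key] = rec.protected

    taxa: set[str] = set()
    for rec in transects:
        for seg in rec.segments:
            if seg.taxon:
                taxa.add(seg.taxon)
    taxa_sorted = sorted(taxa)

    rows = {}
    for key, recs in sorted(groups.items(), key=lambda kv: tuple(map(str, kv[0]))):
        tape = sum(r.transect_length for r in recs)
        cov = dict.fromkeys(taxa_sorted, 0.0)
        for r in recs:
            for seg in r.segments:
                if seg.taxon:
                    cov[seg.taxon] += seg.length
        rows[key] = {t: 100.0 * cov[t] / tape for t in taxa_sorted}

    index = pd.MultiIndex.from_tuples(rows.keys(), names=list(group_by))
    if level == "pooled-year":
        index = pd.Index([k[0] for k in rows], name="year")
    mat = pd.DataFrame.from_dict(rows, orient="index")
    mat.index = index
    mat.attrs["protected"] = {k: prot[k] for k in rows}
    return mat


def resolve_growth_form(
    taxon: str,
    traits: pd.DataFrame,
    tie_break: str = "alphabetical",
) -> str:
    """Growth form for a taxon, via genus mode when not listed directly.

    ``traits`` needs columns ``genus`` and ``growth_form`` indexed by taxon.
    Genus-level records ("Acropora spp.") take the most frequent growth
    form within the genus; ties break alphabetically on the form label.
    """
    if taxon in traits.index:
        return str(traits.loc[taxon, "growth_form"])
    genus = taxon.split()[0]
    members = traits[traits["genus"] == genus]
    if members.empty:
        raise KeyError(f"cannot resolve growth form for taxon {taxon!r}")
    counts = members["growth_form"].value_counts()
    top = counts[counts == counts.max()]
    return sorted(top.index)[0]


def growth_form_cover(matrix: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a taxon cover matrix into cover by growth form.

    Every taxon must resolve to a growth form, either directly or through
    the modal growth form of its genus.  Row sums equal total coral cover.
    """
    unresolved = []
    forms = {}
    for taxon in matrix.columns:
        try:
            forms[taxon] = resolve_growth_form(taxon, traits)
        except KeyError:
            unresolved.append(taxon)
    if unresolved:
        raise KeyError(f"unresolvable growth form for taxa: {unresolved}")
    grouped = matrix.T.groupby(pd.Series(forms)).sum().T
    grouped.attrs = dict(matrix.attrs)
    return grouped


def write_table(df: pd.DataFrame, path: str | Path, provenance: str = "") -> None:
    """Write a result table as TSV with a one-line provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#generated-by reeftraits {provenance}\n")
        df.to_csv(fh, sep="\t")
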