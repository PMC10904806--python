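"""Reading and writing the package's file formats.

Trees travel as Newick (one or more per file, branch lengths in MY);
species and result tables are comma-delimited UTF-8 with a header row.
Tip labels and species names are normalised identically on both sides
before any matching: lowercased, spaces mapped to underscores, and
surrounding quotes stripped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from .phylogeny import Phylogeny, PhylogenyError

__all__ = [
    "RED_LIST_CATEGORIES",
    "DATA_SUFFICIENT_CATEGORIES",
    "THREATENED_CATEGORIES",
    "POPULATION_TRENDS",
    "SpeciesRecord",
    "MatchReport",
    "normalize_name",
    "read_newick",
    "write_newick",
    "read_species_table",
    "write_species_table",
    "records_to_frame",
    "match_tips",
]

#: IUCN Red List categories accepted in species tables.
RED_LIST_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "EW", "EX", "DD", "NE")

#: Categories counting as "data sufficient" assessments.
DATA_SUFFICIENT_CATEGORIES = frozenset({"LC", "NT", "VU", "EN", "CR", "EW"})

#: Threatened categories (EW included alongside VU/EN/CR as the most
#: severe extant-risk state).
THREATENED_CATEGORIES = frozenset({"VU", "EN", "CR", "EW"})

POPULATION_TRENDS = ("decreasing", "stable", "increasing", "unknown")

REQUIRED_COLUMNS = (
    "species", "genus", "family", "clade",
    "red_list_category", "population_trend", "possibly_extinct",
)


def normalize_name(name: str) -> str:
    """Canonical form of a species/tip name: lowercase, underscores, unquoted."""
    return str(name).strip().strip("'\"").strip().lower().replace(" ", "_")


@dataclass(frozen=True)
class SpeciesRecord:
    """One species row: taxonomy, Red List category, trend and flags."""

    species: str
    genus: str
    family: str
    clade: str
    red_list_category: str
    population_trend: str = "unknown"
    possibly_extinct: bool = False

    def __post_init__(self):
        if self.red_list_category not in RED_LIST_CATEGORIES:
            raise ValueError(
                f"unknown Red List category {self.red_list_category!r} "
                f"for species {self.species!r}"
            )
        if self.population_trend not in POPULATION_TRENDS:
            raise ValueError(
                f"unknown population trend {self.population_trend!r} "
                f"for species {self.species!r}"
            )

    @property
    def data_sufficient(self) -> bool:
        """True iff the category is an assessed, data sufficient one."""
        return self.red_list_category in DATA_SUFFICIENT_CATEGORIES

    @property
    def threatened(self) -> bool:
        return self.red_list_category in THREATENED_CATEGORIES

    @property
    def key(self) -> str:
        return normalize_name(self.species)


# ----------------------------------------------------------------------
# Newick I/O
# ----------------------------------------------------------------------

def read_newick(path: str | Path) -> list[Phylogeny]:
    """Read one or more Newick trees, validating each.

    Replicate order in the file is preserved; tree ``k`` gets label
    ``"<stem>#<k>"``.
    """
    path = Path(path)
    try:
        trees = dendropy.TreeList.get(
            path=str(path), schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise PhylogenyError(f"cannot parse Newick file {path}: {exc}") from exc
    out: list[Phylogeny] = []
    for k, tree in enumerate(trees):
        # Validation error messages name the offending record.
        try:
            out.append(Phylogeny(tree, label=f"{path.stem}#{k}"))
        except PhylogenyError as exc:
            raise PhylogenyError(f"{path} (tree {k}): {exc}") from exc
    if not out:
        raise PhylogenyError(f"{path}: no trees found")
    return out


def write_newick(trees: Phylogeny | Iterable[Phylogeny], path: str | Path) -> None:
    if isinstance(trees, Phylogeny):
        trees = [trees]
    with open(path, "w", encoding="utf-8") as fh:
        for t in trees:
            fh.write(t.as_newick() + "\n")


# ----------------------------------------------------------------------
# species tables
# ----------------------------------------------------------------------

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f", ""}


def _parse_bool(value, line_no: int) -> bool:
    s = str(value).strip().lower()
    if s in ("nan", "none"):
        s = ""
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"line {line_no}: cannot parse boolean {value!r}")


def read_species_table(path: str | Path) -> list[SpeciesRecord]:
    """Read a species table (CSV), validating vocabularies row by row.

    Errors name the (1-based, header-inclusive) line of the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: list[SpeciesRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            records.append(SpeciesRecord(
                species=row.species,
                genus=row.genus,
                family=row.family,
                clade=row.clade,
                red_list_category=str(row.red_list_category).strip().upper(),
                population_trend=str(row.population_trend).strip().lower(),
                possibly_extinct=_parse_bool(row.possibly_extinct, line_no),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}, line {line_no}: {exc}") from exc
    return records


def records_to_frame(records: Sequence[SpeciesRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "species": [r.species for r in records],
        "genus": [r.genus for r in records],
        "family": [r.family for r in records],
        "clade": [r.clade for r in records],
        "red_list_category": [r.red_list_category for r in records],
        "population_trend": [r.population_trend for r in records],
        "possibly_extinct": [r.possibly_extinct for r in records],
        "data_sufficient": [r.data_sufficient for r in records],
        "key": [r.key for r in records],
    })


def write_species_table(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    df = records_to_frame(records).drop(columns=["data_sufficient", "key"])
    df.to_csv(path, index=False)


# ----------------------------------------------------------------------
# tip/table reconciliation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MatchReport:
    """Reconciliation of tree tips against species-table names."""

    matched: tuple[str, ...]        # normalised names present on both sides
    tree_only: tuple[str, ...]      # tips with no table row
    table_only: tuple[str, ...]     # rows with no tip (the imputation queue)


def match_tips(trees: Phylogeny | Sequence[Phylogeny],
               records: Sequence[SpeciesRecord]) -> MatchReport:
    """Compare the union of tip labels across trees with the table names."""
    if isinstance(trees, Phylogeny):
        trees = [trees]
    tree_names: set[str] = set()
    for t in trees:
        tree_names.update(normalize_name(lab) for lab in t.tip_labels)
    table_names = {r.key for r in records}
    return MatchReport(
        matched=tuple(sorted(tree_names & table_names)),
        tree_only=tuple(sorted(tree_names - table_names)),
        table_only=tuple(sorted(table_names - tree_names)),
    )
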