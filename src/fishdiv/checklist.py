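"""Checklist, occurrence-matrix, and site-attribute tables.

The analysis operates on three plain CSV tables:

* a taxonomic **checklist** — one row per species with its full rank path
  (phylum, class, order, family, genus) plus optional 0/1 flag columns
  (endemic, cave, threatened, alien, or any new category);
* a binary **occurrence matrix** — one row per species, one 0/1 column per
  site (sub-basin);
* a **site-attribute** table — one row per site with hydrological /
  environmental drivers (river length, watershed area, gradient,
  precipitation, temperature, runoff, altitude).

Validation enforces that the taxonomy is a tree: a genus name maps to exactly
one family, a family to one order, an order to one class, a class to one
phylum.  Site ordering is taken from the occurrence file and preserved in
every downstream table.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: rank columns required in a checklist CSV, child-most last
RANK_COLUMNS = ("species_id", "genus", "family", "order", "class", "phylum")

#: child rank -> parent rank pairs whose mapping must be functional
_PARENT_OF = (
    ("genus", "family"),
    ("family", "order"),
    ("order", "class"),
    ("class", "phylum"),
)

#: canonical site-attribute columns (Table-1 style drivers)
SITE_ATTRIBUTE_COLUMNS = (
    "length_km",
    "area_km2",
    "gradient_pct",
    "precipitation_mm",
    "temperature_C",
    "runoff_1e8m3",
    "altitude_m",
)


class Checklist:
    """A validated species checklist with its taxonomic hierarchy.

    Parameters
    ----------
    frame
        DataFrame with the columns of :data:`RANK_COLUMNS`; any additional
        column is treated as a 0/1 flag column.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in RANK_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"checklist is missing column(s): {', '.join(missing)}")
        for col in RANK_COLUMNS:
            frame[col] = frame[col].astype(str).str.strip()
            empty = frame[col].isin(("", "nan", "None"))
            if empty.any():
                rows = frame.index[empty].tolist()[:5]
                raise ValidationError(f"empty values in rank column {col!r} (rows {rows})")
        dup = frame["species_id"][frame["species_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate species_id: {sorted(set(dup))}")
        flag_cols = [c for c in frame.columns if c not in RANK_COLUMNS]
        for col in flag_cols:
            vals = pd.to_numeric(frame[col], errors="coerce")
            if not vals.isin((0, 1)).all():
                raise FormatError(f"flag column {col!r} must be 0/1")
            frame[col] = vals.astype(int)
        for child, parent in _PARENT_OF:
            n_parents = frame.groupby(child)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise ValidationError(
                    f"{child} name(s) mapped to several {parent} values: "
                    f"{sorted(bad.index.tolist())}"
                )
        self.frame = frame.set_index("species_id", drop=False)
        self.flag_columns = tuple(flag_cols)

    # -- basic counts -----------------------------------------------------
    @property
    def species(self) -> pd.Index:
        return self.frame.index

    def __len__(self) -> int:
        return len(self.frame)

    def rank_counts(self) -> dict[str, int]:
        """Distinct taxa per rank, species included."""
        out = {"species": len(self.frame)}
        for rank in ("genus", "family", "order", "class", "phylum"):
            out[rank] = self.frame[rank].nunique()
        return out

    # -- lookup -----------------------------------------------------------
    def species_in(self, rank: str, name: str) -> pd.Index:
        if rank not in RANK_COLUMNS[1:]:
            raise KeyError(f"unknown rank {rank!r}")
        return self.frame.index[self.frame[rank] == name]

    def flagged(self, flag: str) -> pd.Index:
        if flag not in self.flag_columns:
            raise KeyError(f"unknown flag {flag!r}")
        return self.frame.index[self.frame[flag] == 1]

    def lineage_codes(self, species: Sequence[str] | None = None) -> np.ndarray:
        """Integer codes (n x 5) for genus..phylum, for fast path-length work."""
        if species is None:
            sub = self.frame
        else:
            species = list(species)
            unknown = [s for s in species if s not in self.frame.index]
            if unknown:
                raise ValidationError(f"species not in checklist: {unknown[:5]}")
            sub = self.frame.loc[species]
        cols = []
        for rank in ("genus", "family", "order", "class", "phylum"):
            codes, _ = pd.factorize(sub[rank])
            cols.append(codes)
        return np.stack(cols, axis=1)

    def subset(self, species: Iterable[str]) -> "Checklist":
        species = list(species)
        unknown = [s for s in species if s not in self.frame.index]
        if unknown:
            raise ValidationError(f"species not in checklist: {unknown[:5]}")
        return Checklist(self.frame.loc[species].reset_index(drop=True))


class OccurrenceMatrix:
    """Binary species x site incidence aligned to a :class:`Checklist`."""

    def __init__(self, frame: pd.DataFrame, checklist: Checklist | None = None,
                 allow_empty_sites: bool = False):
        frame = frame.copy()
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].tolist()
            raise ValidationError(f"duplicate species_id rows: {sorted(set(dups))}")
        if frame.columns.has_duplicates:
            dups = frame.columns[frame.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate site columns: {sorted(set(dups))}")
        arr = frame.to_numpy()
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary cell at species {frame.index[r]!r}, site "
                f"{frame.columns[c]!r}: {arr[r, c]!r}"
            )
        frame = frame.astype(np.int8)
        if checklist is not None:
            unknown = frame.index.difference(checklist.species)
            if len(unknown):
                raise ValidationError(
                    f"species absent from checklist: {sorted(unknown.tolist())[:5]}"
                )
        empty = frame.columns[frame.sum(axis=0) == 0]
        if len(empty):
            if not allow_empty_sites:
                raise ValidationError(
                    f"site(s) with zero presences: {empty.tolist()}"
                )
        self.frame = frame
        self.checklist = checklist

    @property
    def sites(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def species(self) -> pd.Index:
        return self.frame.index

    @property
    def n_sites(self) -> int:
        return self.frame.shape[1]

    def richness(self) -> pd.Series:
        """Species count per site (column sums), in site order."""
        return self.frame.sum(axis=0)

    def site_species(self, site: str) -> pd.Index:
        return self.frame.index[self.frame[site] == 1]

    def values_sites_by_species(self) -> np.ndarray:
        """Incidence as a (n_sites, n_species) int array."""
        return self.frame.to_numpy().T

    def occupancy(self) -> pd.Series:
        """Number of sites each species occupies."""
        return self.frame.sum(axis=1)


class SiteAttributes:
    """Per-site numeric drivers; missing cells allowed and propagated."""

    def __init__(self, frame: pd.DataFrame, sites: Sequence[str] | None = None):
        frame = frame.copy()
        if frame.index.has_duplicates:
            raise ValidationError("duplicate site rows in attribute table")
        if sites is not None:
            unknown = [s for s in frame.index if s not in list(sites)]
            if unknown:
                raise ValidationError(f"unknown site(s) in attribute table: {unknown}")
            frame = frame.reindex([s for s in sites if s in frame.index])
        for col in frame.columns:
            vals = pd.to_numeric(frame[col], errors="coerce")
            # every originally non-blank cell must be a finite non-negative number
            blank = frame[col].isna() | (frame[col].astype(str).str.strip() == "")
            nonnum = vals.isna() & ~blank
            if nonnum.any():
                raise FormatError(
                    f"non-numeric value in {col!r} for site(s) "
                    f"{frame.index[nonnum].tolist()}"
                )
            if (vals.dropna() < 0).any():
                raise ValidationError(
                    f"negative value in {col!r} for site(s) "
                    f"{frame.index[vals < 0].tolist()}"
                )
            if np.isinf(vals.dropna()).any():
                raise ValidationError(f"non-finite value in {col!r}")
            frame[col] = vals
        self.frame = frame

    @property
    def sites(self) -> list[str]:
        return list(self.frame.index)

    @property
    def attributes(self) -> list[str]:
        return list(self.frame.columns)


# ---------------------------------------------------------------------------
# readers / writers (UTF-8 CSV throughout)
# ---------------------------------------------------------------------------

def read_checklist(path) -> Checklist:
    """Read and validate a checklist CSV (header row naming the rank columns)."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return Checklist(frame)


def write_checklist(checklist: Checklist, path) -> None:
    checklist.frame.reset_index(drop=True).to_csv(path, index=False)


def read_occurrences(path, checklist: Checklist | None = None,
                     allow_empty_sites: bool = False) -> OccurrenceMatrix:
    """Read a wide binary table (rows = species_id, columns = sites)."""
    frame = pd.read_csv(path)
    if "species_id" not in frame.columns:
        raise FormatError("occurrence table is missing column: species_id")
    frame = frame.set_index("species_id")
    return OccurrenceMatrix(frame, checklist, allow_empty_sites=allow_empty_sites)


def write_occurrences(matrix: OccurrenceMatrix, path) -> None:
    matrix.frame.rename_axis("species_id").to_csv(path)


def read_site_attributes(path, sites: Sequence[str] | None = None) -> SiteAttributes:
    """Read a per-site attribute CSV; blank cells stay missing, never imputed."""
    frame = pd.read_csv(path)
    site_col = frame.columns[0]
    frame = frame.set_index(site_col)
    return SiteAttributes(frame, sites=sites)


def write_site_attributes(attrs: SiteAttributes, path) -> None:
    attrs.frame.rename_axis("site").to_csv(path)


def checklist_from_records(records: Iterable[Mapping[str, object]]) -> Checklist:
    """Build a checklist from an iterable of dict-like records (mostly tests)."""
    return Checklist(pd.DataFrame(list(records)))
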