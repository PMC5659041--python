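"""Presence/absence marker matrices from transposon display.

A transposon-display assay yields one gel band per TE insertion site; each
band is scored 1 (full site, band present) or 0 (empty site) in every
accession.  The matrix is strictly binary: the assay cannot distinguish
"band absent" from "lane failed", so missing values are not representable.

Files are plain delimited text (tab for ``.tsv``/``.txt``, comma for
``.csv``): a mandatory header row of locus ids, the first column holding
accession ids.  The locus -> TE-family annotation travels in ``#family``
comment lines at the top of the same file, or in a separate two-column map.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "MarkerMatrix",
    "PopulationMap",
    "read_marker_table",
    "write_marker_table",
    "read_population_map",
    "write_population_map",
    "read_family_map",
    "subset_accessions",
    "subset_loci",
]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class MarkerMatrix:
    """Binary accession x locus table of TE insertion sites.

    Parameters
    ----------
    values
        DataFrame with accession ids as index, locus ids as columns and
        integer 0/1 entries.
    family_of_locus
        Optional mapping locus id -> TE family label (e.g. ``Fortuna``).
    is_view
        True for row subsets, where the "every locus observed at least
        once" invariant is intentionally not enforced.
    """

    values: pd.DataFrame
    family_of_locus: dict[str, str] = field(default_factory=dict)
    is_view: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        df = self.values
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValidationError("matrix needs at least one accession and one locus")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate accession id(s): {dup}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate locus id(s): {dup}")
        if df.isna().any().any():
            raise ValidationError("missing values are not representable in a marker matrix")
        bad = ~df.isin((0, 1))
        if bad.any().any():
            acc = df.index[bad.any(axis=1)][0]
            loc = df.columns[bad.any(axis=0)][0]
            raise FormatError(
                f"non-binary cell at accession {acc!r}, locus {loc!r}: {df.loc[acc, loc]!r}"
            )
        if not self.is_view:
            dead = df.columns[(df == 0).all(axis=0)].tolist()
            if dead:
                raise ValidationError(
                    f"locus column(s) never observed in any accession: {dead}"
                )
        unknown = set(self.family_of_locus) - set(df.columns)
        if unknown:
            raise ValidationError(f"family map refers to unknown loci: {sorted(unknown)}")

    # -- conveniences ---------------------------------------------------
    @property
    def accession_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_accessions(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def families(self) -> list[str]:
        """Family labels in first-appearance (column) order."""
        seen: dict[str, None] = {}
        for loc in self.values.columns:
            fam = self.family_of_locus.get(loc)
            if fam is not None:
                seen.setdefault(fam, None)
        return list(seen)

    def loci_of_family(self, family: str) -> list[str]:
        loci = [l for l in self.values.columns if self.family_of_locus.get(l) == family]
        if not loci:
            raise ValidationError(f"no loci annotated with family {family!r}")
        return loci

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.family_of_locus == other.family_of_locus


@dataclass
class PopulationMap:
    """Accession -> population label mapping."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValidationError("population map is empty")

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    def population_of(self, accession: str) -> str:
        try:
            return self.assignments[accession]
        except KeyError:
            raise ValidationError(f"accession {accession!r} has no population label") from None

    def accessions_of(self, population: str) -> list[str]:
        accs = [a for a, p in self.assignments.items() if p == population]
        if not accs:
            raise ValidationError(f"population {population!r} has no accessions")
        return accs

    def check_covers(self, matrix: MarkerMatrix | Iterable[str]) -> None:
        """Hard error if any accession lacks a population label."""
        ids = matrix.accession_ids if isinstance(matrix, MarkerMatrix) else list(matrix)
        missing = [a for a in ids if a not in self.assignments]
        if missing:
            raise ValidationError(f"accessions missing from population map: {missing}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_marker_table(source: str | Path | io.TextIOBase, sep: str | None = None) -> MarkerMatrix:
    """Read a presence/absence marker table from delimited text.

    Leading ``#family <locus> <family>`` comment lines are parsed as the
    locus -> family annotation; any other ``#`` line is ignored.
    """
    if isinstance(source, (str, Path)):
        sep = sep or _sep_for(source)
        with open(source, "r", encoding="utf-8") as fh:
            return _read_marker_stream(fh, sep)
    return _read_marker_stream(source, sep or "\t")


def _read_marker_stream(fh: io.TextIOBase, sep: str) -> MarkerMatrix:
    family: dict[str, str] = {}
    body: list[str] = []
    for line in fh:
        if line.startswith("#"):
            parts = line[1:].strip().split(sep)
            if len(parts) == 3 and parts[0] == "family":
                family[parts[1]] = parts[2]
            continue
        if line.strip():
            body.append(line)
    if not body:
        raise FormatError("marker table has no header row")
    try:
        df = pd.read_csv(io.StringIO("".join(body)), sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse marker table: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(int)
    except ValueError:
        for acc in df.index:
            for loc in df.columns:
                cell = df.loc[acc, loc]
                try:
                    int(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"cell at accession {acc!r}, locus {loc!r} is not an integer: {cell!r}"
                    ) from None
        raise
    return MarkerMatrix(df, family_of_locus=family)


def write_marker_table(matrix: MarkerMatrix, sink: str | Path | io.TextIOBase,
                       sep: str | None = None) -> None:
    """Write a marker matrix (family annotations as ``#family`` lines)."""
    if isinstance(sink, (str, Path)):
        sep = sep or _sep_for(sink)
        try:
            with open(sink, "w", encoding="utf-8") as fh:
                _write_marker_stream(matrix, fh, sep)
        except OSError as exc:
            raise OSError(f"cannot write marker table to {sink}: {exc}") from exc
    else:
        _write_marker_stream(matrix, sink, sep or "\t")


def _write_marker_stream(matrix: MarkerMatrix, fh: io.TextIOBase, sep: str) -> None:
    for locus in matrix.locus_ids:
        fam = matrix.family_of_locus.get(locus)
        if fam is not None:
            fh.write(f"#family{sep}{locus}{sep}{fam}\n")
    matrix.values.to_csv(fh, sep=sep, index_label="accession", lineterminator="\n")


def read_population_map(source: str | Path, sep: str | None = None) -> PopulationMap:
    """Read a two-column (accession, population) table."""
    sep = sep or _sep_for(source)
    df = pd.read_csv(source, sep=sep, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError("population map needs two columns: accession, population")
    col_a, col_p = df.columns[:2]
    if df[col_a].duplicated().any():
        dup = df.loc[df[col_a].duplicated(), col_a].tolist()
        raise ValidationError(f"duplicate accession(s) in population map: {dup}")
    return PopulationMap(dict(zip(df[col_a], df[col_p])))


def write_population_map(popmap: PopulationMap, sink: str | Path, sep: str | None = None) -> None:
    sep = sep or _sep_for(sink)
    df = pd.DataFrame(
        {"accession": list(popmap.assignments), "population": list(popmap.assignments.values())}
    )
    df.to_csv(sink, sep=sep, index=False)


def read_family_map(source: str | Path, sep: str | None = None) -> dict[str, str]:
    """Read a two-column (locus, family) table."""
    sep = sep or _sep_for(source)
    df = pd.read_csv(source, sep=sep, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError("family map needs two columns: locus, family")
    col_l, col_f = df.columns[:2]
    if df[col_l].duplicated().any():
        raise ValidationError("duplicate locus in family map")
    return dict(zip(df[col_l], df[col_f]))


# ---------------------------------------------------------------------------
# Subsetting
# ---------------------------------------------------------------------------

def subset_accessions(matrix: MarkerMatrix, keep: Iterable[str]) -> MarkerMatrix:
    """Row-restricted view of the matrix (marked ``is_view``).

    Locus columns are retained even if all-zero within the subset; the
    "observed at least once" invariant applies only to full matrices.
    """
    keep = list(keep)
    if not keep:
        raise ValidationError("cannot subset to an empty accession set")
    unknown = [a for a in keep if a not in matrix.values.index]
    if unknown:
        raise ValidationError(f"unknown accession id(s): {unknown}")
    return MarkerMatrix(
        matrix.values.loc[keep], family_of_locus=dict(matrix.family_of_locus), is_view=True
    )


def subset_loci(matrix: MarkerMatrix, keep: Iterable[str]) -> MarkerMatrix:
    """Column-restricted view (used for per-family analyses)."""
    keep = list(keep)
    if not keep:
        raise ValidationError("cannot subset to an empty locus set")
    unknown = [l for l in keep if l not in matrix.values.columns]
    if unknown:
        raise ValidationError(f"unknown locus id(s): {unknown}")
    fam = {l: f for l, f in matrix.family_of_locus.items() if l in keep}
    return MarkerMatrix(matrix.values[keep], family_of_locus=fam, is_view=True)
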