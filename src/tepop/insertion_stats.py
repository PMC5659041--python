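"""Insertion-polymorphism statistics over marker matrices.

Definitions
-----------
For a locus and a population, the site code is

* ``0`` — empty site in every accession of the population,
* ``1`` — full site in some (but not all) accessions,
* ``2`` — full site in every accession.

Locus status (classes are disjoint, precedence unique > specific >
polymorphic > monomorphic):

* *monomorphic* — full site in every accession of every population;
* *polymorphic* — empty in at least one accession somewhere;
* *population_specific* — additionally, empty in every accession of at
  least one population while present in at least two populations;
* *population_unique* — present in exactly one population.

Polymorphism level for a TE family within a population counts only loci
observed in that population (a band never seen in the population cannot be
scored there): ``level = 100 * polymorphic / total`` with *total* the bands
present in >= 1 accession of the population and *polymorphic* those also
absent in >= 1 accession of it.  The overall level pools all accessions.
Percentages are reported to one decimal, rounding half away from zero.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .marker_matrix import MarkerMatrix, PopulationMap

__all__ = [
    "InsertionClassification",
    "round1",
    "level_percent",
    "locus_population_codes",
    "classify_locus",
    "classify_all",
    "polymorphism_level",
    "polymorphism_table",
    "count_insertion_classes",
    "write_polymorphism_table",
    "write_classification_table",
]

STATUSES = ("monomorphic", "polymorphic", "population_specific", "population_unique")


@dataclass(frozen=True)
class InsertionClassification:
    locus_id: str
    status: str
    population_codes: dict[str, int]

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(f"unknown status {self.status!r}")


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (presentation convention)."""
    return math.floor(abs(x) * 10.0 + 0.5) / 10.0 * (1 if x >= 0 else -1)


def level_percent(polymorphic: int, total: int) -> float:
    """Polymorphism level ``100 * polymorphic / total`` to one decimal."""
    if total <= 0:
        raise UndefinedStatisticError("polymorphism level undefined: no bands in scope")
    if not 0 <= polymorphic <= total:
        raise ValidationError("polymorphic count must lie in [0, total]")
    return round1(100.0 * polymorphic / total)


def locus_population_codes(
    matrix: MarkerMatrix, popmap: PopulationMap, locus: str
) -> dict[str, int]:
    """Per-population 0/1/2 site code for one locus."""
    if locus not in matrix.values.columns:
        raise ValidationError(f"unknown locus {locus!r}")
    popmap.check_covers(matrix)
    col = matrix.values[locus]
    codes: dict[str, int] = {}
    for pop in popmap.populations:
        accs = [a for a in matrix.accession_ids if popmap.assignments[a] == pop]
        if not accs:
            continue
        carriers = int(col.loc[accs].sum())
        codes[pop] = 0 if carriers == 0 else (2 if carriers == len(accs) else 1)
    return codes


def _status_from_codes(codes: dict[str, int]) -> str:
    nonzero = sum(1 for c in codes.values() if c != 0)
    if all(c == 2 for c in codes.values()):
        return "monomorphic"
    if nonzero == 1:
        return "population_unique"
    if any(c == 0 for c in codes.values()) and nonzero >= 2:
        return "population_specific"
    return "polymorphic"


def classify_locus(
    matrix: MarkerMatrix, popmap: PopulationMap, locus: str
) -> InsertionClassification:
    """Classify one locus from its per-population site codes."""
    codes = locus_population_codes(matrix, popmap, locus)
    return InsertionClassification(locus, _status_from_codes(codes), codes)


def classify_all(matrix: MarkerMatrix, popmap: PopulationMap) -> list[InsertionClassification]:
    popmap.check_covers(matrix)
    vals = matrix.values
    pops = popmap.populations
    groups = {p: [a for a in matrix.accession_ids if popmap.assignments[a] == p] for p in pops}
    groups = {p: a for p, a in groups.items() if a}
    out = []
    for locus in matrix.locus_ids:
        col = vals[locus]
        codes = {}
        for pop, accs in groups.items():
            carriers = int(col.loc[accs].sum())
            codes[pop] = 0 if carriers == 0 else (2 if carriers == len(accs) else 1)
        out.append(InsertionClassification(locus, _status_from_codes(codes), codes))
    return out


def polymorphism_level(
    matrix: MarkerMatrix,
    popmap: PopulationMap,
    family: str,
    scope: str = "overall",
) -> dict:
    """One cell of the polymorphism summary: counts and level for a family.

    ``scope`` is ``"overall"`` (all accessions pooled) or a population
    label.  Returns ``{"polymorphic": int, "total": int, "level_percent":
    float}``.
    """
    loci = matrix.loci_of_family(family)
    sub = matrix.values[loci]
    if scope == "overall":
        accs = matrix.accession_ids
    else:
        popmap.check_covers(matrix)
        accs = [a for a in matrix.accession_ids if popmap.assignments[a] == scope]
        if not accs:
            raise ValidationError(f"population {scope!r} has no accessions in the matrix")
    block = sub.loc[accs]
    present = block.sum(axis=0) > 0
    absent_somewhere = (block == 0).any(axis=0)
    if scope == "overall":
        total = len(loci)  # family totals count every scored band
    else:
        total = int(present.sum())
    poly = int((present & absent_somewhere).sum())
    return {"polymorphic": poly, "total": total, "level_percent": level_percent(poly, total)}


def polymorphism_table(matrix: MarkerMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Family x (population + overall) grid of counts and levels.

    Rows are indexed by (family, statistic) with statistics ``polymorphic``,
    ``total`` and ``level_percent``; a grand-total family row ``ALL`` is
    appended.  Cells whose statistic is undefined (no bands of the family in
    a population) are flagged with NaN rather than raising.
    """
    missing = [l for l in matrix.locus_ids if l not in matrix.family_of_locus]
    if missing:
        raise ValidationError(f"loci without family annotation: {missing}")
    popmap.check_covers(matrix)
    scopes = list(popmap.populations) + ["overall"]
    rows = []
    index = []
    fam_cells: dict[str, dict[str, dict]] = {}
    for family in matrix.families:
        fam_cells[family] = {}
        for scope in scopes:
            try:
                fam_cells[family][scope] = polymorphism_level(matrix, popmap, family, scope)
            except UndefinedStatisticError:
                fam_cells[family][scope] = None
    for family in matrix.families:
        for stat in ("polymorphic", "total", "level_percent"):
            row = []
            for scope in scopes:
                cell = fam_cells[family][scope]
                row.append(float("nan") if cell is None else cell[
                    "level_percent" if stat == "level_percent" else stat
                ])
            rows.append(row)
            index.append((family, stat))
    # grand totals pooled over families
    for stat in ("polymorphic", "total"):
        row = []
        for scope in scopes:
            cells = [fam_cells[f][scope] for f in matrix.families]
            row.append(
                float("nan")
                if any(c is None for c in cells)
                else sum(c[stat] for c in cells)
            )
        rows.append(row)
        index.append(("ALL", stat))
    row = []
    for scope in scopes:
        cells = [fam_cells[f][scope] for f in matrix.families]
        if any(c is None for c in cells):
            row.append(float("nan"))
        else:
            row.append(level_percent(sum(c["polymorphic"] for c in cells),
                                     sum(c["total"] for c in cells)))
    rows.append(row)
    index.append(("ALL", "level_percent"))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["family", "statistic"]),
        columns=scopes,
    )


def count_insertion_classes(matrix: MarkerMatrix, popmap: PopulationMap) -> dict:
    """Counts and percentages of insertion classes over all loci.

    Percentages use the total locus count as denominator, to one decimal.
    ``population_specific`` and ``population_unique`` are disjoint.
    """
    classes = classify_all(matrix, popmap)
    n = len(classes)
    counts = {s: 0 for s in STATUSES}
    for c in classes:
        counts[c.status] += 1
    # "polymorphic overall" in the summary sense: everything not monomorphic
    poly_total = n - counts["monomorphic"]
    out = {
        "total_loci": n,
        "polymorphic": poly_total,
        "population_specific": counts["population_specific"],
        "population_unique": counts["population_unique"],
        "percent_polymorphic": round1(100.0 * poly_total / n),
        "percent_population_specific": round1(100.0 * counts["population_specific"] / n),
        "percent_population_unique": round1(100.0 * counts["population_unique"] / n),
    }
    return out


def write_polymorphism_table(table: pd.DataFrame, sink: str | Path | io.TextIOBase,
                             sep: str = "\t") -> None:
    table.to_csv(sink, sep=sep)


def write_classification_table(
    classes: list[InsertionClassification], sink: str | Path | io.TextIOBase, sep: str = "\t"
) -> None:
    """Per-locus status plus 0/1/2 codes, one row per locus."""
    pops = list(classes[0].population_codes) if classes else []
    df = pd.DataFrame(
        [
            {"locus": c.locus_id, "status": c.status, **{p: c.population_codes[p] for p in pops}}
            for c in classes
        ]
    )
    df.to_csv(sink, sep=sep, index=False)
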