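import numpy as np
import pandas as pd
import pytest

from tepop import (
    MarkerMatrix,
    PopulationMap,
    UndefinedStatisticError,
    ValidationError,
    classify_all,
    classify_locus,
    count_insertion_classes,
    locus_population_codes,
    polymorphism_level,
    polymorphism_table,
)
from tepop.insertion_stats import level_percent, round1


def test_population_codes(five_pop_codes_matrix):
    matrix, popmap = five_pop_codes_matrix
    assert locus_population_codes(matrix, popmap, "mono") == {
        p: 2 for p in ["P1", "P2", "P3", "P4", "P5"]
    }
    assert locus_population_codes(matrix, popmap, "uniq")["P2"] == 0
    assert locus_population_codes(matrix, popmap, "spec")["P1"] == 1
    with pytest.raises(ValidationError):
        locus_population_codes(matrix, popmap, "missing")


def test_code_one_means_some_not_all():
    # 3 of 10 accessions carry the insertion -> code 1
    accs = [f"a{i}" for i in range(10)]
    col = [1, 1, 1] + [0] * 7
    df = pd.DataFrame({"L": col, "anchor": [1] * 10}, index=accs)
    pm = PopulationMap({a: "P" for a in accs})
    assert locus_population_codes(MarkerMatrix(df), pm, "L") == {"P": 1}


@pytest.mark.parametrize(
    "locus,status",
    [
        ("mono", "monomorphic"),
        ("uniq", "population_unique"),
        ("spec", "population_specific"),
        ("poly", "polymorphic"),
    ],
)
def test_classification_precedence(five_pop_codes_matrix, locus, status):
    matrix, popmap = five_pop_codes_matrix
    assert classify_locus(matrix, popmap, locus).status == status


def test_polymorphism_level_derived_example():
    # columns (1,1,1), (1,0,1), (0,0,1): total 3, polymorphic 2 -> 66.7%
    df = pd.DataFrame(
        {"L1": [1, 1, 1], "L2": [1, 0, 1], "L3": [0, 0, 1]},
        index=["x", "y", "z"],
    )
    m = MarkerMatrix(df, family_of_locus={c: "F" for c in df.columns})
    pm = PopulationMap({"x": "P", "y": "P", "z": "P"})
    cell = polymorphism_level(m, pm, "F", "overall")
    assert cell == {"polymorphic": 2, "total": 3, "level_percent": 66.7}


def test_single_accession_population_is_monomorphic():
    df = pd.DataFrame({"L1": [1, 0], "L2": [1, 1]}, index=["solo", "other"])
    m = MarkerMatrix(df, family_of_locus={"L1": "F", "L2": "F"})
    pm = PopulationMap({"solo": "One", "other": "Two"})
    cell = polymorphism_level(m, pm, "F", "One")
    assert cell["polymorphic"] == 0 and cell["level_percent"] == 0.0


def test_per_population_total_counts_only_observed_bands(toy_matrix, toy_popmap):
    # L3 (Minos) is present only in the South accession: North totals exclude it
    cell = polymorphism_level(toy_matrix, toy_popmap, "Minos", "North")
    assert cell["total"] == 1  # L4 only
    overall = polymorphism_level(toy_matrix, toy_popmap, "Minos", "overall")
    assert overall["total"] == 2


def test_polymorphism_table_partitions(toy_matrix, toy_popmap):
    table = polymorphism_table(toy_matrix, toy_popmap)
    total_by_family = table.xs("total", level="statistic")["overall"]
    assert total_by_family.loc["ALL"] == toy_matrix.n_loci
    assert (
        total_by_family.drop("ALL").sum() == toy_matrix.n_loci
    )  # families partition the loci
    poly = table.xs("polymorphic", level="statistic")["overall"]
    absent_somewhere = int(((toy_matrix.values == 0).any(axis=0)).sum())
    assert poly.loc["ALL"] == absent_somewhere


def test_count_insertion_classes_toy(five_pop_codes_matrix):
    matrix, popmap = five_pop_codes_matrix
    counts = count_insertion_classes(matrix, popmap)
    assert counts["population_unique"] == 1
    assert counts["population_specific"] == 1
    assert counts["polymorphic"] == 3  # everything but the monomorphic locus
    assert counts["total_loci"] == 4


def test_all_monomorphic_matrix_has_no_classes():
    df = pd.DataFrame(np.ones((4, 3), dtype=int), index=list("abcd"), columns=["x", "y", "z"])
    m = MarkerMatrix(df, family_of_locus={c: "F" for c in df.columns})
    pm = PopulationMap({"a": "P1", "b": "P1", "c": "P2", "d": "P2"})
    counts = count_insertion_classes(m, pm)
    assert counts["polymorphic"] == 0
    assert counts["population_specific"] == 0
    assert counts["population_unique"] == 0


def test_relabeling_populations_permutes_statistics(five_pop_codes_matrix):
    matrix, popmap = five_pop_codes_matrix
    relabeled = PopulationMap({a: "Z" + p for a, p in popmap.assignments.items()})
    c1 = count_insertion_classes(matrix, popmap)
    c2 = count_insertion_classes(matrix, relabeled)
    assert c1 == c2
    codes1 = locus_population_codes(matrix, popmap, "spec")
    codes2 = locus_population_codes(matrix, relabeled, "spec")
    assert {("Z" + p): v for p, v in codes1.items()} == codes2


def test_rounding_half_away_from_zero():
    assert round1(18.75) == 18.8
    assert round1(34.25) == 34.3
    assert level_percent(15, 80) == 18.8
    with pytest.raises(UndefinedStatisticError):
        level_percent(0, 0)


def test_brute_force_recount_on_random_matrices():
    """Table cells equal a direct per-cell recount on random matrices."""
    rng = np.random.default_rng(42)
    for _ in range(10):
        n_acc, n_loc = 12, 15
        vals = rng.binomial(1, 0.6, size=(n_acc, n_loc))
        vals[:, vals.sum(axis=0) == 0] = 1  # keep the observed-once invariant
        accs = [f"a{i}" for i in range(n_acc)]
        df = pd.DataFrame(vals, index=accs, columns=[f"L{j}" for j in range(n_loc)])
        fams = {f"L{j}": ("F1" if j < 7 else "F2") for j in range(n_loc)}
        m = MarkerMatrix(df, family_of_locus=fams)
        pm = PopulationMap({a: ("P1" if i < 6 else "P2") for i, a in enumerate(accs)})
        table = polymorphism_table(m, pm)
        for fam in ("F1", "F2"):
            loci = [l for l, f in fams.items() if f == fam]
            for pop in ("P1", "P2"):
                accs_p = pm.accessions_of(pop)
                block = df.loc[accs_p, loci]
                total = int((block.sum(axis=0) > 0).sum())
                poly = int(((block.sum(axis=0) > 0) & (block == 0).any(axis=0)).sum())
                assert table.loc[(fam, "total"), pop] == total
                assert table.loc[(fam, "polymorphic"), pop] == poly
                assert table.loc[(fam, "level_percent"), pop] == pytest.approx(
                    round1(100 * poly / total)
                )
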