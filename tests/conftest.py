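import numpy as np
import pandas as pd
import pytest

from tepop import MarkerMatrix, PopulationMap


@pytest.fixture
def toy_matrix() -> MarkerMatrix:
    """3 accessions x 4 loci, two families."""
    df = pd.DataFrame(
        [[1, 1, 0, 1], [1, 0, 0, 1], [0, 1, 1, 1]],
        index=["a1", "a2", "b1"],
        columns=["L1", "L2", "L3", "L4"],
    )
    fam = {"L1": "Fortuna", "L2": "Fortuna", "L3": "Minos", "L4": "Minos"}
    return MarkerMatrix(df, family_of_locus=fam)


@pytest.fixture
def toy_popmap() -> PopulationMap:
    return PopulationMap({"a1": "North", "a2": "North", "b1": "South"})


@pytest.fixture
def five_pop_codes_matrix() -> tuple[MarkerMatrix, PopulationMap]:
    """Two accessions in each of five populations; loci built per-population.

    Locus columns realize the canonical code patterns: monomorphic
    (2,2,2,2,2), population-unique (2,0,0,0,0), population-specific
    (1,2,0,0,0), and plain polymorphic (2,2,2,2,1).
    """
    pops = ["P1", "P2", "P3", "P4", "P5"]
    accs = [f"{p}x{i}" for p in pops for i in (1, 2)]
    patterns = {
        "mono": {p: 2 for p in pops},
        "uniq": {"P1": 2, "P2": 0, "P3": 0, "P4": 0, "P5": 0},
        "spec": {"P1": 1, "P2": 2, "P3": 0, "P4": 0, "P5": 0},
        "poly": {"P1": 2, "P2": 2, "P3": 2, "P4": 2, "P5": 1},
    }
    cols = {}
    for name, codes in patterns.items():
        col = []
        for p in pops:
            c = codes[p]
            col += {0: [0, 0], 1: [1, 0], 2: [1, 1]}[c]
        cols[name] = col
    df = pd.DataFrame(cols, index=accs)
    matrix = MarkerMatrix(df, family_of_locus={c: "Fam" for c in cols})
    popmap = PopulationMap({a: a.split("x")[0] for a in accs})
    return matrix, popmap
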