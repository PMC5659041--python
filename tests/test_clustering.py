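import numpy as np
import pandas as pd
import pytest

import dendropy

from tepop import (
    ResemblanceMatrix,
    UndefinedStatisticError,
    ValidationError,
    bray_curtis,
    group_average_cluster,
    simprof_cluster,
    simprof_test,
    to_newick,
)
from tepop.simulate import SimConfig, simulate_marker_matrix
from tepop.marker_matrix import subset_loci


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 1, 0], [1, 1, 0], 100.0),
        ([1, 1, 0], [0, 0, 1], 0.0),
        ([1, 1, 0], [1, 0, 1], 50.0),
    ],
)
def test_bray_curtis_examples(x, y, expected):
    res = bray_curtis(np.array([x, y], dtype=float))
    assert res.similarity[0, 1] == pytest.approx(expected)


def test_bray_curtis_undefined_pair_named():
    X = np.array([[0, 0], [0, 0], [1, 0]], dtype=float)
    with pytest.raises(UndefinedStatisticError, match="S0.*S1"):
        bray_curtis(X)


def test_bray_curtis_symmetry_and_range():
    rng = np.random.default_rng(11)
    X = rng.binomial(1, 0.4, size=(8, 20)).astype(float)
    X[X.sum(axis=1) == 0, 0] = 1
    s = bray_curtis(X).similarity
    assert np.allclose(s, s.T)
    assert s.min() >= 0 and s.max() <= 100


# ---------------------------------------------------------------------------
# Group-average clustering
# ---------------------------------------------------------------------------

def _pair_sim(n, entries):
    s = np.full((n, n), 100.0)
    for (i, j), v in entries.items():
        s[i, j] = s[j, i] = v
    return ResemblanceMatrix([f"s{i}" for i in range(n)], s)


def test_two_samples_single_merge():
    tree = group_average_cluster(_pair_sim(2, {(0, 1): 73.0}))
    assert tree.root.height == 73.0
    assert tree.root.members == (0, 1)


def _oracle_upgma(sim: np.ndarray):
    """Brute-force group-average agglomeration from the original matrix.

    At each step every candidate cluster pair's similarity is recomputed as
    the mean over all original cross-pairs; the most similar pair merges,
    ties broken by lexicographically smallest member tuples.  Returns the
    set of (members, height) merges.
    """
    clusters = [(i,) for i in range(sim.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca, cb = clusters[a], clusters[b]
                s = np.mean([sim[i, j] for i in ca for j in cb])
                key = (-s, tuple(sorted((ca, cb))))
                if best is None or key < best[0]:
                    best = (key, a, b, s)
        _, a, b, s = best
        merged = tuple(sorted(clusters[a] + clusters[b]))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        merges.append((merged, round(s, 9)))
    return sorted(merges)


@pytest.mark.parametrize("trial", range(30))
def test_group_average_matches_bruteforce_oracle(trial):
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(3, 6))
    # half the trials use coarse values to provoke ties
    vals = rng.integers(0, 4, size=(n, n)) * 25.0 if trial % 2 else rng.random((n, n)) * 100
    sim = (vals + vals.T) / 2.0
    np.fill_diagonal(sim, 100.0)
    res = ResemblanceMatrix([f"s{i}" for i in range(n)], sim)
    tree = group_average_cluster(res)
    mine = sorted(
        (node.members, round(node.height, 9)) for node in tree.internal_nodes()
    )
    assert mine == _oracle_upgma(sim)


def test_merge_heights_monotone_rootward():
    rng = np.random.default_rng(7)
    X = rng.binomial(1, 0.5, size=(12, 30)).astype(float)
    X[X.sum(axis=1) == 0, 0] = 1
    tree = group_average_cluster(bray_curtis(X))

    def check(node):
        if node.children:
            for c in node.children:
                assert c.height >= node.height - 1e-9
                check(c)

    check(tree.root)


# ---------------------------------------------------------------------------
# SIMPROF
# ---------------------------------------------------------------------------

def test_identical_rows_give_pi_zero_p_one():
    X = np.tile([1, 0, 1, 1, 0, 0], (5, 1)).astype(float)
    r = simprof_test(X, seed=3)
    assert r.pi == 0.0
    assert r.p_value == 1.0


def test_groups_of_two_are_untestable():
    r = simprof_test(np.array([[1, 0], [0, 1]], dtype=float), seed=0)
    assert not r.testable
    assert r.p_value == 1.0


def test_nonpositive_permutation_counts_rejected():
    with pytest.raises(ValidationError):
        simprof_test(np.ones((4, 3)), n_perm_mean=0)


def test_seed_determinism_bit_identical():
    rng = np.random.default_rng(5)
    X = rng.binomial(1, 0.5, size=(8, 25)).astype(float)
    r1 = simprof_test(X, seed=99)
    r2 = simprof_test(X, seed=99)
    assert r1 == r2
    r3 = simprof_test(X, seed=100)
    assert r3 != r1


def test_separated_blocks_detected():
    """Two well-separated 5-sample blocks are flagged in every tried seed."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        p = np.where(np.arange(40) < 20, 0.9, 0.05)
        X = np.vstack(
            [rng.binomial(1, p, size=(5, 40)), rng.binomial(1, p[::-1], size=(5, 40))]
        ).astype(float)
        r = simprof_test(X, seed=seed)
        hits += r.p_value <= 0.05
    assert hits >= 9


def test_simprof_cluster_structured_matrix_recovers_population_nodes():
    cfg = SimConfig(seed=8, drift_concentration=0.5)
    matrix, popmap, _ = simulate_marker_matrix(cfg)
    sub = subset_loci(matrix, matrix.loci_of_family("Aison"))
    tree = simprof_cluster(sub, n_perm_mean=199, n_perm_null=199, seed=4)
    part = tree.significant_partition()
    # every resulting group should be population-pure under strong structure
    for pop_of in [popmap.assignments]:
        groups = {}
        for acc, g in part.items():
            groups.setdefault(g, set()).add(pop_of[acc])
        assert all(len(pops) == 1 for pops in groups.values())


def test_single_population_contract():
    """A homogeneous subset yields a tested root with well-defined flags."""
    rng = np.random.default_rng(2)
    X = rng.binomial(1, 0.5, size=(6, 30)).astype(float)
    tree = simprof_cluster(X, n_perm_mean=99, n_perm_null=99, seed=0)
    assert tree.root.simprof is not None
    assert tree.root.significant in (True, False)
    for node in tree.nodes():
        assert node.significant in (True, False)


def test_nonsignificant_node_prunes_subtree():
    rng = np.random.default_rng(12)
    X = rng.binomial(1, 0.5, size=(10, 40)).astype(float)
    tree = simprof_cluster(X, n_perm_mean=99, n_perm_null=99, seed=1)
    for node in tree.internal_nodes():
        if not node.significant:
            for desc in node.walk():
                if desc is not node:
                    assert not desc.significant


def test_label_permutation_equivariance():
    """Permuting sample order permutes leaves, not heights or p-values.

    Uses enough loci that all pairwise similarities are distinct, so the
    documented index-based tie-break cannot change the topology.
    """
    rng = np.random.default_rng(21)
    X = rng.binomial(1, 0.5, size=(9, 400)).astype(float)
    ids = [f"s{i}" for i in range(9)]
    df = pd.DataFrame(X, index=ids)
    sims = bray_curtis(df).similarity[np.triu_indices(9, 1)]
    assert len(np.unique(sims)) == len(sims), "fixture must be tie-free"
    perm = rng.permutation(9)
    df2 = df.iloc[perm]
    t1 = simprof_cluster(df, n_perm_mean=99, n_perm_null=99, seed=6)
    t2 = simprof_cluster(df2, n_perm_mean=99, n_perm_null=99, seed=6)

    def node_map(tree):
        return {
            frozenset(tree.sample_ids[i] for i in n.members): (
                round(n.height, 9),
                None if n.simprof is None else n.simprof.p_value,
            )
            for n in tree.internal_nodes()
        }

    assert node_map(t1) == node_map(t2)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def test_two_leaf_newick():
    res = ResemblanceMatrix(["A", "B"], np.array([[100.0, 73.0], [73.0, 100.0]]))
    tree = group_average_cluster(res)
    assert to_newick(tree) == "(A:0.27,B:0.27);"


def test_newick_round_trip_topology():
    rng = np.random.default_rng(3)
    X = rng.binomial(1, 0.5, size=(7, 25)).astype(float)
    ids = [f"acc{i}" for i in range(7)]
    tree = simprof_cluster(pd.DataFrame(X, index=ids),
                           n_perm_mean=99, n_perm_null=99, seed=0)
    text = to_newick(tree)
    parsed = dendropy.Tree.get(data=text, schema="newick")
    assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == sorted(ids)
    # clades agree
    clades = {
        frozenset(l.taxon.label for l in n.leaf_iter())
        for n in parsed.preorder_internal_node_iter()
    }
    mine = {
        frozenset(tree.sample_ids[i] for i in n.members) for n in tree.internal_nodes()
    }
    assert mine == clades


def test_fifty_leaf_newick_valid():
    cfg = SimConfig(seed=1)
    matrix, _, _ = simulate_marker_matrix(cfg)
    sub = subset_loci(matrix, matrix.loci_of_family("Minos"))
    tree = group_average_cluster(bray_curtis(sub))
    parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
    assert len(parsed.leaf_nodes()) == 50
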