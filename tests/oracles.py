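"""Independent brute-force oracles shared by unit and acceptance tests."""

import itertools

import numpy as np


def upgma_oracle(sim: np.ndarray):
    """Group-average agglomeration recomputed from the original matrix.

    Every step re-averages all original cross-pairs for every candidate
    cluster pair (no incremental updates), merging the most similar pair
    with ties broken toward the lexicographically smallest member tuples.
    Returns sorted [(members, height)] merges.
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
        merges.append((merged, round(float(s), 9)))
    return sorted(merges)


def maximal_nonsignificant_cliques(groups, flags):
    """All maximal sets with no significant internal pair (by enumeration)."""
    cliques = []
    for r in range(1, len(groups) + 1):
        for sub in itertools.combinations(groups, r):
            if all(not flags[frozenset(p)] for p in itertools.combinations(sub, 2)):
                cliques.append(frozenset(sub))
    return {c for c in cliques if not any(c < d for d in cliques)}


def sorensen_closed_form(V: np.ndarray):
    """Binary Sorensen similarity 100 * 2a / (2a + b + c) for all row pairs.

    ``a`` counts shared presences, ``b``/``c`` private presences; returns a
    full matrix with NaN where the form is undefined (both rows empty).
    """
    V = np.asarray(V, dtype=float)
    a = V @ V.T
    r = V.sum(axis=1)
    b = r[:, None] - a
    c = r[None, :] - a
    denom = 2 * a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, 100.0 * 2.0 * a / np.where(denom > 0, denom, 1), np.nan)
    return out
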