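"""Bray-Curtis resemblance, group-average clustering and the SIMPROF test.

The workflow mirrors the resemblance-based clustering used for binary
insertion-site matrices: pairwise Bray-Curtis similarity (for 0/1 data the
Sorensen coefficient ``100 * 2a / (2a + b + c)``), group-average (UPGMA)
agglomeration on similarities, and a similarity-profile (SIMPROF)
permutation test applied top-down over dendrogram nodes.  A node whose
member set shows no evidence of internal structure (p >= alpha) is marked
non-significant together with its whole subtree, and descent stops there —
the classic black/red line annotation of resemblance dendrograms.

SIMPROF, for a group of g samples: the observed profile is the g(g-1)/2
pairwise similarities sorted ascending.  Each permutation independently
shuffles every locus's values across the g samples (variables are never
permuted against each other); the expected profile is the rank-wise mean of
sorted profiles over ``n_perm_mean`` permutations.  The test statistic is
``pi = sum over ranks |observed - expected|``; ``n_perm_null`` fresh
permutations yield null deviations against the same expected profile, and
``p = (1 + #{null >= pi}) / (1 + n_perm_null)`` (add-one estimator, so p is
never exactly 0).  Groups of size <= 2 are untestable: a profile of a
single similarity cannot support the test.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import UndefinedStatisticError, ValidationError
from .marker_matrix import MarkerMatrix

__all__ = [
    "ResemblanceMatrix",
    "SimprofResult",
    "Node",
    "Dendrogram",
    "bray_curtis",
    "group_average_cluster",
    "simprof_test",
    "simprof_cluster",
    "to_newick",
    "write_resemblance",
]

# cap on the elements of one permutation batch, keeps memory ~100 MB
_BATCH_ELEMENTS = 4_000_000


@dataclass
class ResemblanceMatrix:
    """Symmetric pairwise similarity on a 0..100 scale, diagonal 100."""

    sample_ids: list[str]
    similarity: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.similarity, dtype=float)
        n = len(self.sample_ids)
        if s.shape != (n, n):
            raise ValidationError("similarity matrix shape does not match sample ids")
        if not np.allclose(s, s.T, atol=1e-9):
            raise ValidationError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(s), 100.0, atol=1e-9):
            raise ValidationError("similarity diagonal must be 100")
        if s.min() < -1e-9 or s.max() > 100 + 1e-9:
            raise ValidationError("similarities must lie in [0, 100]")
        self.similarity = s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.similarity, index=self.sample_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SimprofResult:
    pi: float
    p_value: float
    n_perm_mean: int
    n_perm_null: int
    testable: bool = True


@dataclass
class Node:
    """Dendrogram node; leaves have height 100 and no children."""

    members: tuple[int, ...]          # original sample indices, sorted
    height: float                     # merge similarity; 100 for leaves
    children: tuple["Node", "Node"] | None = None
    simprof: SimprofResult | None = None
    significant: bool | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def walk(self) -> Iterator["Node"]:
        yield self
        if self.children:
            for c in self.children:
                yield from c.walk()


@dataclass
class Dendrogram:
    root: Node
    sample_ids: list[str]

    def nodes(self) -> list[Node]:
        return list(self.root.walk())

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.root.walk() if not n.is_leaf]

    def node_table(self) -> pd.DataFrame:
        """Members, merge height and SIMPROF annotation per internal node."""
        rows = []
        for node in self.internal_nodes():
            sp = node.simprof
            rows.append(
                {
                    "members": ",".join(self.sample_ids[i] for i in node.members),
                    "n": len(node.members),
                    "height": node.height,
                    "pi": sp.pi if sp else float("nan"),
                    "p_value": sp.p_value if sp else float("nan"),
                    "tested": sp is not None and sp.testable,
                    "significant": bool(node.significant),
                }
            )
        return pd.DataFrame(rows)

    def significant_partition(self) -> dict[str, int]:
        """Group labels induced by pruning at non-significant nodes.

        Starting from the root, a node flagged significant is split into its
        children; any other node contributes its whole member set as one
        group.  Requires :func:`simprof_cluster` annotations.
        """
        groups: list[tuple[int, ...]] = []

        def visit(node: Node) -> None:
            if node.significant and node.children is not None:
                for c in node.children:
                    visit(c)
            else:
                groups.append(node.members)

        visit(self.root)
        out: dict[str, int] = {}
        for gi, members in enumerate(groups):
            for i in members:
                out[self.sample_ids[i]] = gi
        return out


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def _as_matrix(data: MarkerMatrix | pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, MarkerMatrix):
        return data.values.to_numpy(dtype=float), data.accession_ids
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(i) for i in data.index]
    arr = np.asarray(data, dtype=float)
    return arr, [f"S{i}" for i in range(arr.shape[0])]


def bray_curtis(data: MarkerMatrix | pd.DataFrame | np.ndarray) -> ResemblanceMatrix:
    """Pairwise Bray-Curtis similarity, ``100 * (1 - sum|x-y| / sum(x+y))``.

    For binary rows this equals the Sorensen coefficient
    ``100 * 2a / (2a + b + c)``.  A pair of rows with ``sum(x+y) = 0`` has
    no defined similarity and raises :class:`UndefinedStatisticError`.
    """
    X, ids = _as_matrix(data)
    if X.shape[0] < 2:
        raise ValidationError("resemblance needs at least two samples")
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        a, b = ids[zero_rows[0]], ids[zero_rows[1]]
        raise UndefinedStatisticError(
            f"Bray-Curtis undefined for pair ({a!r}, {b!r}): both rows are all-zero"
        )
    sim = 100.0 * (1.0 - squareform(pdist(X, metric="braycurtis")))
    np.fill_diagonal(sim, 100.0)
    return ResemblanceMatrix(ids, sim)


def write_resemblance(res: ResemblanceMatrix, sink: str | Path | io.TextIOBase,
                      sep: str = "\t") -> None:
    res.to_frame().to_csv(sink, sep=sep, index_label="sample")


# ---------------------------------------------------------------------------
# Group-average (UPGMA) agglomeration on similarities
# ---------------------------------------------------------------------------

def group_average_cluster(res: ResemblanceMatrix) -> Dendrogram:
    """Agglomerate by maximum group-average similarity.

    Between-cluster similarity is the arithmetic mean of all cross-pair
    similarities, maintained exactly via the size-weighted (Lance-Williams)
    update.  Ties on similarity are broken deterministically in favour of
    the pair whose sorted member-index tuples compare lexicographically
    smallest.
    """
    n = len(res.sample_ids)
    if n < 2:
        raise ValidationError("clustering needs at least two samples")
    sim: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            sim[(i, j)] = float(res.similarity[i, j])
    clusters: dict[int, Node] = {
        i: Node(members=(i,), height=100.0) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    next_id = n
    while len(clusters) > 1:
        keys = list(clusters)
        best: tuple[int, int] | None = None
        best_s = -np.inf
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                s = sim[(min(a, b), max(a, b))]
                if s > best_s + 1e-12:
                    best, best_s = (a, b), s
                elif abs(s - best_s) <= 1e-12 and best is not None:
                    cand = tuple(sorted((clusters[a].members, clusters[b].members)))
                    cur = tuple(sorted((clusters[best[0]].members, clusters[best[1]].members)))
                    if cand < cur:
                        best = (a, b)
        a, b = best  # type: ignore[misc]
        ca, cb = clusters.pop(a), clusters.pop(b)
        first, second = sorted((ca, cb), key=lambda c: c.members)
        merged = Node(
            members=tuple(sorted(ca.members + cb.members)),
            height=best_s,
            children=(first, second),
        )
        na, nb = sizes.pop(a), sizes.pop(b)
        for k in clusters:
            ka = sim.pop((min(k, a), max(k, a)))
            kb = sim.pop((min(k, b), max(k, b)))
            sim[(min(k, next_id), max(k, next_id))] = (na * ka + nb * kb) / (na + nb)
        sim.pop((min(a, b), max(a, b)))
        clusters[next_id] = merged
        sizes[next_id] = na + nb
        next_id += 1
    (root,) = clusters.values()
    return Dendrogram(root=root, sample_ids=list(res.sample_ids))


# ---------------------------------------------------------------------------
# SIMPROF
# ---------------------------------------------------------------------------

def _sorted_profiles(Xp: np.ndarray) -> np.ndarray:
    """Ascending similarity profiles for a batch of permuted groups.

    ``Xp`` has shape (P, g, L) with binary entries.  Pairs whose combined
    presence count is zero are assigned similarity 0 (they can arise only
    inside permutations; observed data is screened beforehand).
    """
    a = Xp @ Xp.transpose(0, 2, 1)          # shared presences
    r = Xp.sum(axis=2)                       # row totals
    g = Xp.shape[1]
    iu, ju = np.triu_indices(g, k=1)
    denom = r[:, iu] + r[:, ju]
    num = 2.0 * a[:, iu, ju]
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, 100.0 * num / np.where(denom > 0, denom, 1.0), 0.0)
    s.sort(axis=1)
    return s


def _permuted_profiles(X: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Profiles of ``n_perm`` within-locus permutations, batched for memory."""
    g, L = X.shape
    batch = max(1, min(n_perm, _BATCH_ELEMENTS // max(1, g * L)))
    out = []
    done = 0
    while done < n_perm:
        p = min(batch, n_perm - done)
        keys = rng.random((p, g, L))
        idx = np.argsort(keys, axis=1)
        Xp = np.take_along_axis(np.broadcast_to(X, (p, g, L)), idx, axis=1)
        out.append(_sorted_profiles(Xp))
        done += p
    return np.concatenate(out, axis=0)


def simprof_test(
    rows: np.ndarray | pd.DataFrame | MarkerMatrix,
    n_perm_mean: int = 999,
    n_perm_null: int = 999,
    seed: int | np.random.Generator | None = 0,
) -> SimprofResult:
    """Similarity-profile permutation test for one candidate group."""
    if n_perm_mean <= 0 or n_perm_null <= 0:
        raise ValidationError("permutation counts must be positive")
    X, _ = _as_matrix(rows)
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValidationError("SIMPROF operates on binary presence/absence data")
    g = X.shape[0]
    if g <= 2:
        return SimprofResult(pi=0.0, p_value=1.0, n_perm_mean=n_perm_mean,
                             n_perm_null=n_perm_null, testable=False)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = _sorted_profiles(X[None, :, :])[0]
    expected = _permuted_profiles(X, n_perm_mean, rng).mean(axis=0)
    pi = float(np.abs(observed - expected).sum())
    null_profiles = _permuted_profiles(X, n_perm_null, rng)
    null_pi = np.abs(null_profiles - expected[None, :]).sum(axis=1)
    p = (1.0 + int((null_pi >= pi - 1e-12).sum())) / (1.0 + n_perm_null)
    return SimprofResult(pi=pi, p_value=p, n_perm_mean=n_perm_mean,
                         n_perm_null=n_perm_null, testable=True)


def simprof_cluster(
    data: MarkerMatrix | pd.DataFrame | np.ndarray,
    n_perm_mean: int = 999,
    n_perm_null: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> Dendrogram:
    """Cluster samples and annotate every node with SIMPROF significance.

    Top-down traversal: the root's member set is tested first; a node with
    ``p < alpha`` is marked significant and its children are tested in turn;
    otherwise the node and its entire subtree are marked non-significant and
    descent stops.  Each node's rows are canonicalized by sample id and its
    RNG keyed on (seed, member ids), so the result depends neither on
    traversal order nor on the row order of the input.
    """
    X, ids = _as_matrix(data)
    res = bray_curtis(data)
    tree = group_average_cluster(res)

    def visit(node: Node, blocked: bool) -> None:
        if node.is_leaf:
            node.significant = False
            return
        if blocked:
            node.significant = False
            for c in node.children:
                visit(c, True)
            return
        order = sorted(node.members, key=lambda i: ids[i])
        key = zlib.crc32("\x00".join(ids[i] for i in order).encode())
        rng = np.random.default_rng([int(seed), key])
        result = simprof_test(X[order], n_perm_mean, n_perm_null, rng)
        node.simprof = result
        node.significant = result.testable and result.p_value < alpha
        for c in node.children:
            visit(c, not node.significant)

    visit(tree.root, False)
    return tree


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(x, ".6g")

def _comment(node: Node) -> str:
    if node.simprof is None:
        return ""
    sp = node.simprof
    sig = "yes" if node.significant else "no"
    return f"[&pi={_fmt(sp.pi)},p={_fmt(sp.p_value)},significant={sig}]"


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick text with branch lengths ``(100 - merge similarity) / 100``.

    Internal-node comments (``[&pi=...,p=...,significant=...]``) carry the
    SIMPROF annotation and are ignored by standard newick parsers.
    """
    ids = dendrogram.sample_ids

    def render(node: Node, parent_height: float) -> str:
        # branch length = dissimilarity gap to the parent merge, on [0, 1]
        length = (node.height - parent_height) / 100.0
        if node.is_leaf:
            label = ids[node.members[0]]
            return f"{label}:{_fmt(length)}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}){_comment(node)}:{_fmt(length)}"

    root = dendrogram.root
    if root.is_leaf:
        return f"{ids[root.members[0]]};"
    inner = ",".join(render(c, root.height) for c in root.children)
    return f"({inner}){_comment(root)};"
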