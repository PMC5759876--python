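"""Core-gene supertree construction.

Per-family trees are built by neighbor joining on p-distance matrices
computed from pre-aligned protein sequences, combined into a majority-rule
consensus supertree, and rooted on a designated outgroup.  Trees are
carried as dendropy objects; construction of NJ and of the consensus is
implemented here (deterministic tie-breaks throughout), with library
implementations reserved for independent cross-checks in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "p_distance_matrix",
    "neighbor_joining",
    "majority_consensus",
    "root_with_outgroup",
    "build_supertree",
    "bipartition_frequencies",
]

#: characters ignored (in either sequence) when counting differing sites
AMBIGUOUS_CHARS = frozenset("X?-.*")


def p_distance_matrix(alignment: Mapping[str, str]) -> pd.DataFrame:
    """Pairwise p-distances from an alignment (taxon -> sequence).

    d(i, j) is the proportion of differing sites among positions where
    neither sequence has an ambiguity/gap character.
    """
    taxa = sorted(alignment)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    lengths = {t: len(alignment[t]) for t in taxa}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"unequal sequence lengths: {lengths}")
    if lengths[taxa[0]] == 0:
        raise ValueError("empty sequences")

    arr = np.array([list(alignment[t].upper()) for t in taxa])
    ok = ~np.isin(arr, list(AMBIGUOUS_CHARS))
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            d[i, j] = d[j, i] = (
                float((arr[i][both] != arr[j][both]).sum()) / m if m else 0.0
            )
    return pd.DataFrame(d, index=taxa, columns=taxa)


def _as_matrix(dist: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    labels = list(dist.index)
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or list(dist.columns) != labels:
        raise ValueError("distance matrix must be square with matching labels")
    return labels, d


def neighbor_joining(dist: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    Ties in the Q-matrix resolve to the lowest-index pair (row-major);
    negative branch lengths are clamped to 0, with the deficit transferred
    to the sister branch so path lengths are conserved.
    """
    labels, d = _as_matrix(dist)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    # each active node is represented by a growing newick fragment
    frags = {i: labels[i] for i in range(n)}
    active = list(range(n))
    dmat = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj = max(lj + li, 0.0)
            li = 0.0
        elif lj < 0:
            li = max(li + lj, 0.0)
            lj = 0.0
        return li, lj

    while len(active) > 3:
        r = len(active)
        totals = {i: sum(dmat[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dmat[i, j] - totals[i] - totals[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * dmat[i, j] + (totals[i] - totals[j]) / (2 * (r - 2))
        lj = dmat[i, j] - li
        li, lj = clamp(li, lj)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dmat[i, k] + dmat[j, k] - dmat[i, j])
            dmat[u, k] = dmat[k, u] = max(duk, 0.0)
        dmat[u, u] = 0.0
        frags[u] = f"({frags[i]}:{li:.10f},{frags[j]}:{lj:.10f})"
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (dmat[i, j] + dmat[i, k] - dmat[j, k])
    lj = 0.5 * (dmat[i, j] + dmat[j, k] - dmat[i, k])
    lk = 0.5 * (dmat[i, k] + dmat[j, k] - dmat[i, j])
    li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    newick = f"({frags[i]}:{li:.10f},{frags[j]}:{lj:.10f},{frags[k]}:{lk:.10f});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def _splits_of(tree: dendropy.Tree) -> dict[frozenset[str], float | None]:
    """Non-trivial splits of a tree, keyed by the leaf side not containing
    the lexicographically smallest taxon; values are edge lengths."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    splits: dict[frozenset[str], float | None] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        if 1 < len(side) < len(leaves) - 1:
            length = node.edge.length
            splits[side] = length
    return splits


def bipartition_frequencies(
    trees: Sequence[dendropy.Tree],
) -> pd.DataFrame:
    """Frequency table of non-trivial bipartitions across a tree set."""
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for s in _splits_of(t):
            counts[s] = counts.get(s, 0) + 1
    rows = [
        {"bipartition": "|".join(sorted(s)), "count": c,
         "frequency_pct": 100.0 * c / len(trees)}
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["bipartition", "count", "frequency_pct"])


def majority_consensus(
    trees: Sequence[dendropy.Tree],
    threshold: float = 0.5,
    extended: bool = False,
) -> dendropy.Tree:
    """Majority-rule consensus with clade supports.

    Retains exactly the bipartitions present in strictly more than
    ``threshold`` of the input trees (for threshold >= 0.5 these are
    mutually compatible, so the consensus always exists).  Support values
    (percent of trees containing the clade) are stored as internal node
    labels.  Consensus branch lengths are the mean over the trees
    containing the split; unsupported edges get 0.  With
    ``extended=True``, remaining splits are greedily added in frequency
    order when compatible (ties resolved towards the lexicographically
    smallest split).
    """
    if not trees:
        raise ValueError("need at least one tree")
    if not 0.5 <= threshold < 1.0:
        raise ValueError(
            "threshold must be in [0.5, 1): below 0.5 the retained splits "
            "are not guaranteed mutually compatible"
        )
    leafsets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in trees]
    base = leafsets[0]
    for k, ls in enumerate(leafsets[1:], start=2):
        if ls != base:
            diff = sorted(base ^ ls)
            raise ValueError(
                f"tree {k} has a different leaf set; symmetric difference: {diff}"
            )

    counts: dict[frozenset[str], int] = {}
    lengths: dict[frozenset[str], list[float]] = {}
    for t in trees:
        for s, ln in _splits_of(t).items():
            counts[s] = counts.get(s, 0) + 1
            if ln is not None:
                lengths.setdefault(s, []).append(float(ln))

    n = len(trees)
    kept = {s for s, c in counts.items() if c / n > threshold}
    if extended:
        rest = sorted(
            (s for s in counts if s not in kept),
            key=lambda s: (-counts[s], sorted(s)),
        )

        def compatible(a: frozenset[str], b: frozenset[str]) -> bool:
            # two splits (sides not containing the anchor) are compatible
            # iff nested or disjoint
            return a <= b or b <= a or not (a & b)

        for s in rest:
            if all(compatible(s, k) for k in kept):
                kept.add(s)

    # build the consensus top-down: insert splits from largest to smallest
    taxa = sorted(base)
    anchor = taxa[0]

    @dataclass
    class _CNode:
        members: frozenset[str]
        support: float | None
        length: float
        children: list
        leaf: str | None = None

    root = _CNode(members=frozenset(taxa), support=None, length=0.0, children=[])
    for s in sorted(kept, key=lambda s: (-len(s), sorted(s))):
        node = root
        while True:
            child = next(
                (c for c in node.children if c.leaf is None and s < c.members), None
            )
            if child is None:
                break
            node = child
        newnode = _CNode(
            members=s,
            support=100.0 * counts[s] / n,
            length=float(np.mean(lengths[s])) if lengths.get(s) else 0.0,
            children=[c for c in node.children if c.members <= s],
        )
        node.children = [c for c in node.children if not (c.members <= s)]
        node.children.append(newnode)

    # attach leaves
    def attach_leaves(node: _CNode, available: set[str]) -> None:
        for c in node.children:
            attach_leaves(c, available)
        covered = set().union(*(c.members for c in node.children)) if node.children else set()
        for t in sorted(node.members - covered):
            if t in available:
                node.children.append(
                    _CNode(members=frozenset([t]), support=None, length=0.0,
                           children=[], leaf=t)
                )
                available.discard(t)

    attach_leaves(root, set(taxa))

    def to_newick(node: _CNode) -> str:
        if node.leaf is not None:
            return f"{node.leaf}:{node.length:.10f}"
        inner = ",".join(to_newick(c) for c in sorted(
            node.children, key=lambda c: min(c.members)))
        label = "" if node.support is None else f"{node.support:.10g}"
        return f"({inner}){label}:{node.length:.10f}"

    newick = to_newick(root) + ";"
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )
    tree.is_rooted = False
    _ = anchor  # anchor fixed the split orientation above
    return tree


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root a tree on the branch leading to the outgroup (at its midpoint)."""
    clone = tree.clone(depth=1)
    node = next(
        (lf for lf in clone.leaf_node_iter() if lf.taxon.label == outgroup), None
    )
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    edge = node.edge
    half = (edge.length or 0.0) / 2.0
    clone.reroot_at_edge(edge, length1=half, length2=half,
                         update_bipartitions=False)
    clone.is_rooted = True
    return clone


def build_supertree(
    alignments: Mapping[str, Mapping[str, str]],
    outgroup: str,
    threshold: float = 0.5,
    extended: bool = False,
    single_copy: Sequence[str] | None = None,
) -> tuple[dendropy.Tree, list[dendropy.Tree], pd.DataFrame]:
    """Per-family NJ trees -> majority consensus -> outgroup rooting.

    ``alignments`` maps family id -> (taxon -> aligned sequence); families
    can be restricted to ``single_copy`` ids.  Families missing the
    outgroup are skipped with a warning.  Returns the rooted consensus
    supertree, the per-family trees, and the bipartition frequency table.
    """
    fam_ids = sorted(single_copy) if single_copy is not None else sorted(alignments)
    trees: list[dendropy.Tree] = []
    for fid in fam_ids:
        aln = alignments[fid]
        if outgroup not in aln:
            warnings.warn(f"family {fid} lacks the outgroup {outgroup!r}; skipped")
            continue
        trees.append(neighbor_joining(p_distance_matrix(aln)))
    if not trees:
        raise ValueError("no usable families (all lack the outgroup)")
    consensus = majority_consensus(trees, threshold=threshold, extended=extended)
    rooted = root_with_outgroup(consensus, outgroup)
    freqs = bipartition_frequencies(trees)
    return rooted, trees, freqs
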