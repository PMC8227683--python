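"""Distance-based tree estimation and topology checks.

Neighbor joining is used deliberately as a consistent, fully deterministic
estimator for clade-recovery checks on synthetic data (full ML/Bayesian
inference is out of scope here).  Trees are dendropy objects throughout;
newick is the interchange format.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np

from .saturation import DistanceMatrix


class SentinelDistanceError(ValueError):
    """Distance matrix contains undefined (NaN) entries."""


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor-joining agglomeration.

    Ties in the Q criterion are broken by lexicographic taxon-pair order
    (each cluster labelled by its lexicographically smallest leaf).
    Negative branch lengths are clamped to 0 with the deficit moved to the
    sibling branch.  The unrooted result has a trifurcating root.
    """
    taxa = list(d.taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    bad = [
        (taxa[i], taxa[j])
        for i in range(n)
        for j in range(i)
        if not math.isfinite(d.values[i, j])
    ]
    if bad:
        raise SentinelDistanceError(f"undefined distances for pairs: {bad}")

    D = d.values.astype(float).copy()
    newick_of = {i: taxa[i].replace(" ", "_") for i in range(n)}
    label_of = {i: taxa[i] for i in range(n)}  # lexicographic cluster label
    active = list(range(n))

    def join_pair() -> None:
        nonlocal D
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - totals[ai] - totals[aj]
                i, j = active[ai], active[aj]
                key = tuple(sorted((label_of[i], label_of[j])))
                cand = (q, key, ai, aj)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        if m > 2:
            li = 0.5 * dij + (totals[ai] - totals[aj]) / (2 * (m - 2))
        else:
            li = 0.5 * dij
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = max(li + lj, 0.0), 0.0
        new_idx = D.shape[0]
        row = 0.5 * (D[i, :] + D[j, :] - dij)
        D2 = np.zeros((new_idx + 1, new_idx + 1))
        D2[:new_idx, :new_idx] = D
        D2[new_idx, :new_idx] = row
        D2[:new_idx, new_idx] = row
        D = D2
        newick_of[new_idx] = (
            f"({newick_of[i]}:{li:.10f},{newick_of[j]}:{lj:.10f})"
        )
        label_of[new_idx] = min(label_of[i], label_of[j])
        active.remove(i)
        active.remove(j)
        active.append(new_idx)

    while len(active) > 3:
        join_pair()
    if len(active) == 3:
        a, b, c = active
        da = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        db = 0.5 * (D[a, b] + D[b, c] - D[a, c])
        dc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
        da, db, dc = (max(x, 0.0) for x in (da, db, dc))
        newick = (
            f"({newick_of[a]}:{da:.10f},{newick_of[b]}:{db:.10f},"
            f"{newick_of[c]}:{dc:.10f});"
        )
    else:  # exactly 2 clusters remain (n == 3 handled above; n == 2 invalid)
        a, b = active
        newick = f"({newick_of[a]}:{D[a, b] / 2:.10f},{newick_of[b]}:{D[a, b] / 2:.10f});"
    return dendropy.Tree.get(data=newick, schema="newick")


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def is_monophyletic(tree: dendropy.Tree, taxa: set[str], outgroup: str) -> bool:
    """True iff *taxa* form an exact clade after rooting on *outgroup*.

    Singleton sets are monophyletic by convention.  Unknown labels raise.
    """
    labels = leaf_labels(tree)
    unknown = (set(taxa) | {outgroup}) - labels
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if len(taxa) <= 1:
        return True
    work = tree.clone(depth=1)
    og = work.find_node_with_taxon_label(outgroup)
    work.reroot_at_edge(og.edge, update_bipartitions=False)
    mrca = work.mrca(taxa=[work.taxon_namespace.get_taxon(t) for t in taxa])
    clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return clade == set(taxa)


def _nontrivial_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Each internal edge as the smaller-or-canonical side of its split."""
    all_leaves = frozenset(leaf_labels(tree))
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: bipartitions present in exactly one tree."""
    if leaf_labels(t1) != leaf_labels(t2):
        raise ValueError("trees have different leaf sets")
    b1, b2 = _nontrivial_bipartitions(t1), _nontrivial_bipartitions(t2)
    return len(b1 ^ b2)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
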