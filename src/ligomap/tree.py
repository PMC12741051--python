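"""Ward hierarchy construction, fractional cutting, bootstrap supports,
family assignment, and Newick round-tripping.

The sklearn-style :class:`FamilyClassifier` wraps the whole
tree-build/cut/annotate stage; the module functions underneath are usable on
their own.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClusterMixin

from .datatypes import ClusterTree, DistanceMatrix, LigomapError, Partition


def build_tree(d: DistanceMatrix) -> ClusterTree:
    """Ward minimum-variance hierarchy on a (scaled) distance matrix."""
    if d.n < 2:
        raise LigomapError("need at least two leaves")
    if not np.isfinite(d.values).all():
        raise LigomapError("distance matrix must be finite")
    z = hierarchy.linkage(d.condensed(), method="ward")
    return ClusterTree(d.labels, z)


def cut_fractional(tree: ClusterTree, h: float) -> Partition:
    """Cut at fraction ``h`` of the maximum merge height.

    Clusters are the connected components after removing merges with height
    above ``h * max_height``; h = 1 yields one cluster.
    """
    if not 0.0 < h <= 1.0:
        raise LigomapError("h must lie in (0, 1]")
    t = h * tree.max_height()
    flat = hierarchy.fcluster(tree.linkage, t=t, criterion="distance")
    return Partition.from_labels(tree.labels, (int(c) for c in flat))


def _bipartitions(tree: ClusterTree) -> list[frozenset]:
    """One side of each internal node's bipartition (the leafset under it)."""
    return tree.node_leafsets()


def bootstrap_support(
    d: DistanceMatrix,
    n_reps: int = 500,
    seed: int = 0,
    tree: Optional[ClusterTree] = None,
) -> ClusterTree:
    """Attach leaf-resampling bootstrap supports to the Ward tree of ``d``.

    Each replicate resamples leaves with replacement (deduplicated), rebuilds
    the tree on the induced sub-matrix, and checks for every reference node
    whether its bipartition - restricted to the replicate's leaves, requiring
    at least two leaves per side - is present among the replicate tree's
    bipartitions. Support is the fraction of scorable replicates containing it.
    """
    if d.n < 4:
        raise LigomapError("bootstrap requires at least 4 leaves")
    if n_reps < 1:
        raise LigomapError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    ref = tree if tree is not None else build_tree(d)
    ref_sides = _bipartitions(ref)
    all_leaves = frozenset(d.labels)
    present = np.zeros(len(ref_sides))
    scorable = np.zeros(len(ref_sides))
    n = d.n
    for _ in range(n_reps):
        picked = np.unique(rng.integers(0, n, size=n))
        if len(picked) < 4:
            continue
        sub_labels = tuple(d.labels[i] for i in picked)
        sub = DistanceMatrix(
            sub_labels, d.values[np.ix_(picked, picked)], d.measure_id, d.scaled
        )
        rep_tree = build_tree(sub)
        rep_leaves = frozenset(sub_labels)
        rep_sides = set()
        for side in _bipartitions(rep_tree):
            other = rep_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                rep_sides.add(side)
                rep_sides.add(other)
        for k, side in enumerate(ref_sides):
            a = side & rep_leaves
            b = (all_leaves - side) & rep_leaves
            if len(a) < 2 or len(b) < 2:
                continue
            scorable[k] += 1
            if a in rep_sides:
                present[k] += 1
    with np.errstate(invalid="ignore"):
        supports = np.where(scorable > 0, present / np.maximum(scorable, 1), np.nan)
    supports = np.nan_to_num(supports, nan=0.0)
    return ClusterTree(ref.labels, ref.linkage, supports=supports)


def assign_families(partition: Partition, class_labels: Partition) -> pd.DataFrame:
    """Family table: majority class, purity, and outliers per cluster.

    Families are numbered by decreasing size within their majority class
    (e.g. RING1 is the largest RING-majority family).
    """
    if partition.elements != class_labels.elements:
        raise LigomapError("partition and class labels must cover the same elements")
    clusters = partition.clusters()
    rows = []
    for cid, members in clusters.items():
        labels = [class_labels.assignment[m] for m in members]
        counts: dict = {}
        for l in labels:
            counts[l] = counts.get(l, 0) + 1
        majority = max(sorted(counts), key=lambda l: counts[l])
        purity = counts[majority] / len(members)
        outliers = sorted(m for m in members if class_labels.assignment[m] != majority)
        rows.append(
            {
                "majority_class": majority,
                "size": len(members),
                "purity": purity,
                "members": ",".join(sorted(members)),
                "outliers": ",".join(outliers),
                "singleton": len(members) == 1,
            }
        )
    rows.sort(key=lambda r: (str(r["majority_class"]), -r["size"], r["members"]))
    ranks: dict = {}
    for r in rows:
        c = r["majority_class"]
        ranks[c] = ranks.get(c, 0) + 1
        r["family"] = f"{c}{ranks[c]}"
    df = pd.DataFrame(rows)
    return df[["family", "majority_class", "size", "purity", "members", "outliers", "singleton"]]


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def to_newick(tree: ClusterTree) -> str:
    """Newick text with merge-height branch lengths and supports as node labels."""
    n = tree.n_leaves
    heights = np.concatenate([np.zeros(n), tree.linkage[:, 2]])

    def render(node: int) -> str:
        if node < n:
            return tree.labels[node]
        k = node - n
        a, b = int(tree.linkage[k, 0]), int(tree.linkage[k, 1])
        parts = []
        for child in (a, b):
            bl = float(heights[node] - heights[child])
            parts.append(f"{render(child)}:{bl!r}")
        label = "" if tree.supports is None else repr(float(tree.supports[k]))
        return f"({parts[0]},{parts[1]}){label}"

    return render(2 * n - 2) + ";"


def from_newick(text: str) -> ClusterTree:
    """Parse an ultrametric binary Newick string back into a ClusterTree."""
    import dendropy

    try:
        t = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as e:
        raise LigomapError(f"malformed Newick: {e}") from e

    root = t.seed_node
    depth: dict = {root: 0.0}
    for node in t.preorder_node_iter():
        if node is not root:
            depth[node] = depth[node.parent_node] + float(node.edge.length or 0.0)
    leaf_depth = max(depth[l] for l in t.leaf_node_iter())

    entries = []  # (height, support, child_nodes)
    labels = []
    leaf_index: dict = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            leaf_index[node] = len(labels)
            labels.append(node.taxon.label if node.taxon else node.label)
        else:
            kids = node.child_nodes()
            if len(kids) != 2:
                raise LigomapError("tree must be strictly binary")
            support = float(node.label) if node.label not in (None, "") else None
            entries.append((leaf_depth - depth[node], support, node))

    entries.sort(key=lambda e: e[0])
    n = len(labels)
    node_id = dict(leaf_index)
    z = np.zeros((n - 1, 4))
    supports = []
    sizes = {node: 1 for node in leaf_index}
    for k, (height, support, node) in enumerate(entries):
        a, b = node.child_nodes()
        ia, ib = node_id[a], node_id[b]
        size = sizes[a] + sizes[b]
        z[k] = [min(ia, ib), max(ia, ib), height, size]
        node_id[node] = n + k
        sizes[node] = size
        supports.append(support)
    sup = None
    if any(s is not None for s in supports):
        sup = np.array([0.0 if s is None else s for s in supports])
    return ClusterTree(tuple(labels), z, supports=sup)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class FamilyClassifier(ClusterMixin, BaseEstimator):
    """Hierarchical family classification of a precomputed distance matrix.

    Fit builds the Ward tree, optionally attaches bootstrap supports, and
    cuts at the fractional height ``h`` into families.

    Parameters
    ----------
    h : fractional tree cutoff in (0, 1].
    n_bootstrap : bootstrap replicates for branch supports (0 disables).
    random_state : seed for the bootstrap resampling.
    """

    def __init__(self, h: float = 0.25, n_bootstrap: int = 0, random_state: int = 0):
        self.h = h
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    def fit(self, X: DistanceMatrix, y: Optional[Sequence] = None):
        """Fit on a DistanceMatrix; ``y`` (optional) are class labels per leaf."""
        if not isinstance(X, DistanceMatrix):
            X = DistanceMatrix(
                tuple(str(i) for i in range(len(X))), np.asarray(X), "input", scaled=True
            )
        self.tree_ = build_tree(X)
        if self.n_bootstrap:
            self.tree_ = bootstrap_support(
                X, n_reps=self.n_bootstrap, seed=self.random_state, tree=self.tree_
            )
        self.partition_ = cut_fractional(self.tree_, self.h)
        self.labels_ = np.asarray(self.partition_.labels_for(X.labels))
        if y is not None:
            classes = Partition.from_labels(X.labels, y)
            self.family_table_ = assign_families(self.partition_, classes)
        return self

    def newick(self) -> str:
        return to_newick(self.tree_)
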