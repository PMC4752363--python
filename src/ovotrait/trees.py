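"""Phylogenetic trees: pure-birth simulation, newick I/O and the Brownian-motion
tip covariance matrix.

Trees are held as :class:`dendropy.Tree` objects throughout the package. The
covariance construction assumes a rooted tree with branch lengths; under
Brownian motion with rate sigma^2 the tip values are multivariate normal with
covariance sigma^2 * V, where V[i, j] is the root-to-MRCA path length shared by
tips i and j.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np

__all__ = [
    "simulate_yule_tree",
    "tree_height",
    "is_ultrametric",
    "tree_covariance",
    "read_newick",
    "write_newick",
]


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dendropy.Tree:
    """Simulate an ultrametric pure-birth (Yule) tree with ``n_tips`` tips.

    Starting from a single lineage, while ``k`` lineages exist the waiting
    time to the next speciation is exponential with rate ``k * birth_rate``
    and a uniformly chosen lineage bifurcates.  After the n-th lineage
    appears one further exponential interval is simulated and every extant
    lineage is extended to that time, so no tip branch has zero length.  The
    initial single-lineage interval is kept as the root (stem) edge length.

    Parameters
    ----------
    n_tips
        Number of extant tips; must be >= 2.
    birth_rate
        Per-lineage speciation rate (events per unit time); must be > 0.
    seed, rng
        Either an integer seed or an explicit numpy Generator.  Identical
        seeds give bit-identical trees.

    Returns
    -------
    dendropy.Tree
        Rooted, ultrametric, with tips labelled ``sp001`` ... ``spNNN``.
    """
    if n_tips < 2:
        raise ValueError(f"n_tips must be >= 2, got {n_tips}")
    if birth_rate <= 0:
        raise ValueError(f"birth_rate must be > 0, got {birth_rate}")
    if rng is None:
        rng = np.random.default_rng(seed)

    tree = dendropy.Tree()
    root = tree.seed_node
    t = 0.0
    birth_time: dict = {root: 0.0}
    active = [root]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        # for the root this is the stem (single-lineage) interval
        parent.edge.length = t - birth_time[parent]
        children = []
        for _ in range(2):
            child = parent.new_child()
            birth_time[child] = t
            children.append(child)
        # keep lineage order stable: replace parent slot with its children
        active[idx:idx] = children
    # final interval while n_tips lineages exist; tips end at this time
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    taxon_namespace = tree.taxon_namespace
    for i, leaf in enumerate(active, start=1):
        leaf.edge.length = t - birth_time[leaf]
        taxon = taxon_namespace.new_taxon(label=f"sp{i:03d}")
        leaf.taxon = taxon
    return tree


def tree_height(tree: dendropy.Tree, include_stem: bool = False) -> float:
    """Maximum root-to-tip path length; optionally adds the root edge."""
    heights = _tip_depths(tree)
    h = max(heights.values())
    if include_stem and tree.seed_node.edge.length is not None:
        h += tree.seed_node.edge.length
    return h


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-9) -> bool:
    depths = np.array(list(_tip_depths(tree).values()))
    h = depths.max()
    if h == 0:
        return True
    return bool(np.all(np.abs(depths - h) <= rel_tol * h))


def _tip_depths(tree: dendropy.Tree) -> dict:
    """Depth of every leaf below the root (root edge excluded)."""
    depth = {tree.seed_node: 0.0}
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            raise ValueError(f"branch without length at node {node}")
        depth[node] = depth[node.parent_node] + node.edge.length
        if node.is_leaf():
            out[node] = depth[node]
    return out


def tree_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion tip covariance matrix of a rooted tree.

    ``V[i, j]`` is the path length from the root to the most recent common
    ancestor of tips i and j; the diagonal holds root-to-tip depths.  The
    root (stem) edge is excluded, as in the standard construction.

    Returns
    -------
    (V, labels)
        ``V`` is an (n, n) float array, ``labels`` the tip labels in row
        order.
    """
    depth = {tree.seed_node: 0.0}
    leaves: list = []
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            if node.edge.length is None:
                raise ValueError("tree has a branch without a length")
            depth[node] = depth[node.parent_node] + node.edge.length
        if node.is_leaf():
            leaves.append(node)
    index = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    # postorder: tip sets per node; cross-child pairs share that node's depth
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node]
            V[i, i] = depth[node]
            tipsets[node] = [i]
            continue
        child_sets = [tipsets.pop(c) for c in node.child_nodes()]
        d = depth[node]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                for i in child_sets[a]:
                    for j in child_sets[b]:
                        V[i, j] = V[j, i] = d
        merged = [i for s in child_sets for i in s]
        tipsets[node] = merged
    labels = [leaf.taxon.label if leaf.taxon is not None else "" for leaf in leaves]
    return V, labels


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def covariance_for_labels(
    tree: dendropy.Tree, labels: Sequence[str]
) -> np.ndarray:
    """Covariance matrix reordered to match ``labels``.

    Raises ``ValueError`` listing offending species when the tree tips and the
    requested labels do not match one-to-one.
    """
    V, tip_labels = tree_covariance(tree)
    pos = {lab: i for i, lab in enumerate(tip_labels)}
    missing = [lab for lab in labels if lab not in pos]
    extra = [lab for lab in tip_labels if lab not in set(labels)]
    if missing or extra:
        raise ValueError(
            "species mismatch between data and tree: "
            f"absent from tree {missing!r}; absent from data {extra!r}"
        )
    order = [pos[lab] for lab in labels]
    return V[np.ix_(order, order)]
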