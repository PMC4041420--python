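"""Phylogeny plumbing: Newick IO (via dendropy), an array-based tree index
for likelihood computations, the Brownian-motion covariance matrix and
Pagel's lambda transform.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np


def read_newick(source) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths; accepts a path or string."""
    if isinstance(source, dendropy.Tree):
        return source
    s = str(source)
    if "(" in s or ";" in s:
        text = s
    else:
        text = Path(source).read_text()
    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(tree.as_string(schema="newick", suppress_rooting=True))


class TreeIndex:
    """Array view of a rooted tree for fast traversal.

    Nodes are numbered in postorder (root last); tips carry their taxon
    labels. Branch lengths are those of the edge above each node (0 for the
    root). Polytomies are resolved arbitrarily with zero-length branches, and
    missing branch lengths are treated as errors except on the root edge.
    """

    def __init__(self, tree: dendropy.Tree, prune_to: list[str] | None = None):
        tree = tree.clone(depth=1)
        if prune_to is not None:
            taxa = set(prune_to)
            tree.retain_taxa_with_labels(list(taxa))
        tree.resolve_polytomies(update_bipartitions=False)
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self._node_of = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.branch_length = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.labels: list[str | None] = [None] * self.n_nodes
        tip_ids = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                bl = nd.edge.length
                if bl is None:
                    raise ValueError("tree has a missing branch length")
                if bl < 0:
                    raise ValueError("tree has a negative branch length")
                self.branch_length[i] = float(bl)
                p = self._node_of[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise ValueError("unlabeled tip")
                self.labels[i] = nd.taxon.label
                tip_ids.append(i)
        self.root = self.n_nodes - 1
        self.tips = np.array(tip_ids, dtype=int)
        self.tip_labels = [self.labels[i] for i in self.tips]
        self.tip_index = {lab: i for lab, i in zip(self.tip_labels, self.tips)}
        # depths from root
        self.depth = np.zeros(self.n_nodes)
        for i in reversed(range(self.n_nodes)):  # preorder
            if self.parent[i] >= 0:
                self.depth[i] = self.depth[self.parent[i]] + self.branch_length[i]

    def postorder(self):
        return range(self.n_nodes)

    def preorder(self):
        return reversed(range(self.n_nodes))

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def descendant_tips(self, node: int) -> list[str]:
        """Tip labels below (and including) a node."""
        out, stack = [], [node]
        while stack:
            i = stack.pop()
            if self.is_tip(i):
                out.append(self.labels[i])
            else:
                stack.extend(self.children[i])
        return out

    def is_ancestor(self, a: int, b: int) -> bool:
        """True when node ``a`` is a proper ancestor of node ``b``."""
        p = self.parent[b]
        while p >= 0:
            if p == a:
                return True
            p = self.parent[p]
        return False

    def mrca(self, a: int, b: int) -> int:
        anc = set()
        i = a
        while i >= 0:
            anc.add(i)
            i = self.parent[i]
        i = b
        while i not in anc:
            i = self.parent[i]
        return i

    def branch_ids(self) -> np.ndarray:
        """All non-root nodes, each identifying the branch above it."""
        return np.array([i for i in range(self.n_nodes) if i != self.root], dtype=int)

    def patristic_matrix(self) -> np.ndarray:
        """Tip-to-tip path-length distances, ordered as ``tip_labels``."""
        n = len(self.tips)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m = self.mrca(self.tips[i], self.tips[j])
                dist = self.depth[self.tips[i]] + self.depth[self.tips[j]] - 2 * self.depth[m]
                d[i, j] = d[j, i] = dist
        return d


def tree_vcv(tree, tip_order: list[str] | None = None):
    """Brownian-motion covariance of the tips: entry (i, j) is the shared
    root-to-MRCA path length, the diagonal the root-to-tip depth.

    Returns ``(labels, V)``. ``tree`` may be a dendropy Tree, Newick string
    or :class:`TreeIndex`.
    """
    idx = tree if isinstance(tree, TreeIndex) else TreeIndex(read_newick(tree))
    labels = list(idx.tip_labels)
    order = labels if tip_order is None else list(tip_order)
    pos = {lab: k for k, lab in enumerate(order)}
    n = len(order)
    V = np.zeros((n, n))
    # accumulate: every branch adds its length to all tip pairs below it
    below: list[list[int]] = [[] for _ in range(idx.n_nodes)]
    for i in idx.postorder():
        if idx.is_tip(i):
            below[i] = [pos[idx.labels[i]]]
        else:
            below[i] = [t for c in idx.children[i] for t in below[c]]
        if idx.parent[i] >= 0 and idx.branch_length[i] > 0:
            sel = np.array(below[i], dtype=int)
            V[np.ix_(sel, sel)] += idx.branch_length[i]
    return order, V


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda: multiply off-diagonal covariances by ``lam`` in [0, 1]."""
    if not 0 <= lam <= 1:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    W = lam * np.asarray(V, dtype=float)
    np.fill_diagonal(W, np.diag(V))
    return W
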