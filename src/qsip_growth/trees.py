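"""Array-backed tree algebra for the phylogenetic statistics.

`TreeArrays` flattens a dendropy tree into index arrays once, so the
statistics (sister-difference sums, Brownian simulations, the Brownian
covariance matrix, cophenetic distances) run as vectorised numpy over many
traits at a time. Tips occupy indices 0..n_tips-1; internal nodes follow in
postorder with the root last.
"""

from __future__ import annotations

import dendropy
import numpy as np

from .errors import ValidationError
from .model import Phylogeny
from .util import derive_seed


class TreeArrays:
    def __init__(self, tip_names, parent, edge_len, children, postorder_internal):
        self.tip_names = list(tip_names)
        self.n_tips = len(tip_names)
        self.parent = parent
        self.edge_len = edge_len
        self.children = children  # list of lists, indexed by node
        self.postorder_internal = postorder_internal  # internal nodes, root last
        self.n_nodes = len(parent)
        self.tip_index = {n: i for i, n in enumerate(tip_names)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_phylogeny(cls, phylo: Phylogeny | dendropy.Tree) -> "TreeArrays":
        tree = phylo.tree if isinstance(phylo, Phylogeny) else phylo
        leaves = [nd for nd in tree.leaf_node_iter()]
        internals = [nd for nd in tree.postorder_internal_node_iter()]
        order = {id(nd): i for i, nd in enumerate(leaves)}
        for j, nd in enumerate(internals):
            order[id(nd)] = len(leaves) + j
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=int)
        edge_len = np.zeros(n)
        children: list[list[int]] = [[] for _ in range(n)]
        for nd in tree.preorder_node_iter():
            i = order[id(nd)]
            if nd.parent_node is not None:
                parent[i] = order[id(nd.parent_node)]
                edge_len[i] = nd.edge.length or 0.0
                children[parent[i]].append(i)
        tip_names = [lf.taxon.label for lf in leaves]
        postorder_internal = np.array([order[id(nd)] for nd in internals], dtype=int)
        return cls(tip_names, parent, edge_len, children, postorder_internal)

    def trait_vector(self, trait) -> np.ndarray:
        """Map {tip name: value} (or an aligned array) onto tip order."""
        if isinstance(trait, dict):
            missing = [n for n in trait if n not in self.tip_index]
            if missing:
                raise ValidationError(f"trait key(s) not tree tips: {missing[:5]}")
            if len(trait) != self.n_tips:
                raise ValidationError(
                    f"trait covers {len(trait)} of {self.n_tips} tips")
            return np.array([float(trait[n]) for n in self.tip_names])
        arr = np.asarray(trait, dtype=float)
        if arr.shape[0] != self.n_tips:
            raise ValidationError("trait vector length != number of tips")
        return arr

    # -- geometry ----------------------------------------------------------

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        depth = np.zeros(self.n_nodes)
        # parents of preorder nodes are always processed first: walk root-down
        for i in self._preorder():
            p = self.parent[i]
            if p >= 0:
                depth[i] = depth[p] + self.edge_len[i]
        return depth

    def _preorder(self):
        root = self.postorder_internal[-1]
        stack, out = [root], []
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.children[i])
        return out

    def vcv(self) -> np.ndarray:
        """Brownian covariance: C[i, j] = shared root-to-MRCA path length."""
        depth = self.node_depths()
        C = np.zeros((self.n_tips, self.n_tips))
        tipsets: dict[int, list[int]] = {i: [i] for i in range(self.n_tips)}
        for nd in self.postorder_internal:
            groups = [tipsets.pop(ch) for ch in self.children[nd]]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia = np.array(groups[a])[:, None]
                    ib = np.array(groups[b])[None, :]
                    C[ia, ib] = depth[nd]
                    C[ib.T, ia.T] = depth[nd]
            tipsets[nd] = [t for g in groups for t in g]
        np.fill_diagonal(C, depth[:self.n_tips])
        return C

    def cophenetic(self) -> np.ndarray:
        """Patristic (branch-length) distance between every pair of tips."""
        C = self.vcv()
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2 * C

    def height(self) -> float:
        return float(self.node_depths()[:self.n_tips].max())

    # -- simulation and statistics ------------------------------------------

    def simulate_bm(self, n_traits: int, rng: np.random.Generator) -> np.ndarray:
        """Brownian traits: root value 0, variance accrues with branch length.

        Returns an (n_tips, n_traits) matrix.
        """
        vals = np.zeros((self.n_nodes, n_traits))
        noise = rng.standard_normal((self.n_nodes, n_traits))
        for i in self._preorder():
            p = self.parent[i]
            if p >= 0:
                vals[i] = vals[p] + noise[i] * np.sqrt(self.edge_len[i])
        return vals[:self.n_tips]

    def sister_diff_sums(self, tip_values: np.ndarray) -> np.ndarray:
        """Sum of sister-clade differences, vectorised over trait columns.

        Node values are formed by successively averaging descendant values up
        the tree (branch lengths ignored); each internal node contributes the
        summed absolute deviation of its children from their mean, which for
        a bifurcation is |left − right|.
        """
        tv = np.atleast_2d(tip_values.T).T  # (n_tips, k)
        vals = np.zeros((self.n_nodes, tv.shape[1]))
        vals[:self.n_tips] = tv
        total = np.zeros(tv.shape[1])
        for nd in self.postorder_internal:
            ch = self.children[nd]
            sub = vals[ch]
            mean = sub.mean(axis=0)
            vals[nd] = mean
            total += np.abs(sub - mean[None, :]).sum(axis=0)
        return total


def simulate_yule(n_taxa: int, seed: int, tip_prefix: str = "OTU") -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_taxa`` extant tips, unit height.

    Lineages split at rate 1 each; after the tree reaches ``n_taxa`` tips the
    pending branches are extended by one further exponential waiting time, so
    terminal branch lengths are strictly positive. The tree is ultrametric by
    construction and rescaled to height 1. Reproducible: the same seed gives
    byte-identical newick.
    """
    if n_taxa < 4:
        raise ValidationError("need at least 4 taxa for a usable tree")
    rng = np.random.default_rng(derive_seed(seed, "yule", n_taxa))
    tree = dendropy.Tree()
    tree.is_rooted = True
    root = tree.seed_node
    birth_time = {}
    t = 0.0
    active = []
    for _ in range(2):  # the root split defines time zero
        child = dendropy.Node()
        root.add_child(child)
        birth_time[id(child)] = 0.0
        active.append(child)
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        node.edge.length = t - birth_time[id(node)]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth_time[id(child)] = t
            active.append(child)
    t += rng.exponential(1.0 / len(active))
    for i, node in enumerate(active, start=1):
        node.edge.length = t - birth_time[id(node)]
        node.taxon = tree.taxon_namespace.new_taxon(f"{tip_prefix}{i:04d}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / t
    root.edge.length = None
    return Phylogeny(tree)
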