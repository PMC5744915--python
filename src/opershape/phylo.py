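"""Time-calibrated trees, squared-change-parsimony ancestral states,
phylomorphospace layout, and Brownian-motion simulation.

Trees are parsed and written with dendropy but held internally as flat
preorder arrays (parent index, branch length, label), which keeps the
linear-algebra-heavy operations (ancestral-state solves, tree covariance,
batched trait simulation) fast. Branch lengths are in time units (My for
the teleost tree); comparative statistics assume an ultrametric tree.

Squared-change parsimony minimizes the sum of squared state changes along
branches — here branch-length weighted (each squared change divided by its
branch length), the Brownian-motion-consistent variant used by
Mesquite-style phylomorphospaces. The unweighted variant is available via
``weighted=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

import dendropy

__all__ = [
    "TimeTree",
    "AncestralStates",
    "PhylomorphospaceLayout",
    "read_newick",
    "prune_to",
    "ancestral_scp",
    "ScpSolver",
    "phylomorphospace",
    "bm_simulate",
]

_ZERO_BRANCH_FACTOR = 1e-8


class TimeTree:
    """Rooted tree with branch lengths, stored as preorder arrays.

    Node 0 is the root; ``parent[i]`` is the preorder index of node *i*'s
    parent (-1 for the root) and ``blen[i]`` the length of the branch above
    node *i*. Tips carry their taxon labels; unlabeled internal nodes get
    stable ``nd<i>`` identifiers. Polytomies are accepted as-is.
    """

    def __init__(self, parent: np.ndarray, blen: np.ndarray, labels: list[str],
                 is_tip: np.ndarray):
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        self.labels = list(labels)
        self.is_tip = np.asarray(is_tip, dtype=bool)
        if np.any(self.blen[1:] < 0):
            raise ValueError("negative branch lengths")
        self.n_nodes = len(self.labels)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            self.children[self.parent[i]].append(i)
        self.tip_indices = np.flatnonzero(self.is_tip)
        self._vcv_full: np.ndarray | None = None
        self._label_to_index = {self.labels[i]: i for i in self.tip_indices}
        if len(self._label_to_index) != len(self.tip_indices):
            raise ValueError("duplicate tip labels")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TimeTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        blen = np.zeros(n)
        labels: list[str] = []
        is_tip = np.zeros(n, dtype=bool)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                is_tip[i] = True
                if nd.taxon is None or not nd.taxon.label:
                    raise ValueError("unlabeled tip in tree")
                labels.append(nd.taxon.label)
            else:
                lbl = nd.label if nd.label else f"nd{i}"
                labels.append(lbl)
        return cls(parent, blen, labels, is_tip)

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        for i in range(self.n_nodes):
            if self.is_tip[i]:
                dnodes[i].taxon = taxa.new_taxon(self.labels[i])
            if i > 0:
                dnodes[self.parent[i]].add_child(dnodes[i])
                dnodes[i].edge.length = self.blen[i]
        tree.seed_node = dnodes[0]
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick",
                                            suppress_rooting=True).strip()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # -- basic queries -----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    def tip_index(self, label: str) -> int:
        try:
            return self._label_to_index[label]
        except KeyError:
            raise KeyError(f"taxon not in tree: {label!r}") from None

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths, preorder."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.blen[i]
        return d

    @property
    def depth(self) -> float:
        """Maximum root-to-tip depth."""
        return float(self.depths()[self.tip_indices].max())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        td = self.depths()[self.tip_indices]
        return bool(td.max() - td.min() <= rel_tol * max(td.max(), 1e-300))

    def path_to_root(self, node: int) -> list[int]:
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(self.parent[path[-1]])
        return path

    def mrca(self, a: int, b: int) -> int:
        ancestors = set(self.path_to_root(a))
        node = b
        while node not in ancestors:
            node = self.parent[node]
        return node

    def subtree_nodes(self, node: int) -> list[int]:
        """All nodes in the clade rooted at ``node`` (preorder), inclusive."""
        out = []
        stack = [node]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(reversed(self.children[i]))
        return out

    def vcv(self, taxa: Sequence[str] | None = None) -> np.ndarray:
        """Phylogenetic covariance matrix (depths of pairwise MRCAs).

        Symmetric PSD; the diagonal holds root-to-tip depths. Row/column
        order follows ``taxa`` (default: ``tip_labels``). The full matrix
        is cached per tree (trees are treated as immutable).
        """
        if self._vcv_full is None:
            depths = self.depths()
            tip_pos = {int(t): j for j, t in enumerate(self.tip_indices)}
            n = self.n_tips
            C = np.zeros((n, n))
            below: list[np.ndarray | None] = [None] * self.n_nodes
            # reversed preorder visits all descendants before their parent
            for i in reversed(range(self.n_nodes)):
                if self.is_tip[i]:
                    j = tip_pos[i]
                    below[i] = np.array([j])
                    C[j, j] = depths[i]
                else:
                    kids = [below[c] for c in self.children[i]]
                    for a in range(len(kids)):
                        for b in range(a + 1, len(kids)):
                            C[np.ix_(kids[a], kids[b])] = depths[i]
                            C[np.ix_(kids[b], kids[a])] = depths[i]
                    below[i] = np.concatenate(kids)
            self._vcv_full = C
        if taxa is None:
            return self._vcv_full
        pos = {t: j for j, t in enumerate(self.tip_labels)}
        missing = [t for t in taxa if t not in pos]
        if missing:
            raise KeyError(f"taxa not in tree: {missing}")
        perm = [pos[t] for t in taxa]
        return self._vcv_full[np.ix_(perm, perm)]

    def patristic(self, taxa: Sequence[str] | None = None) -> np.ndarray:
        """Pairwise tip-to-tip path-length matrix."""
        if taxa is None:
            taxa = self.tip_labels
        depths = self.depths()
        idx = [self.tip_index(t) for t in taxa]
        C = self.vcv(taxa)
        d = depths[idx]
        return d[:, None] + d[None, :] - 2.0 * C

    def effective_blen(self) -> np.ndarray:
        """Branch lengths with zero-length branches nudged to a tiny epsilon."""
        b = self.blen.copy()
        zero = (b[1:] <= 0)
        if zero.any():
            eps = _ZERO_BRANCH_FACTOR * max(self.depth, 1.0)
            warnings.warn(
                f"{int(zero.sum())} zero-length branch(es) replaced by {eps:g}",
                stacklevel=2,
            )
            b[1:][zero] = eps
        return b


def read_newick(path: str | Path) -> TimeTree:
    """Read a Newick tree file with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return TimeTree.from_dendropy(tree)


def prune_to(tree: TimeTree, taxa: Sequence[str]) -> TimeTree:
    """Prune the tree to ``taxa``, preserving root-to-tip path lengths.

    Unbranched internal nodes left behind are collapsed with their branch
    lengths summed.
    """
    missing = [t for t in taxa if t not in tree._label_to_index]
    if missing:
        raise KeyError(f"taxa not in tree: {missing}")
    dtree = tree.to_dendropy()
    keep = set(taxa)
    dtree.retain_taxa_with_labels(list(keep))
    # collapse a root with a single child (retain_taxa can leave one)
    while dtree.seed_node.num_child_nodes() == 1:
        child = dtree.seed_node.child_nodes()[0]
        child.edge.length = None
        dtree.seed_node = child
        child.parent_node = None
    return TimeTree.from_dendropy(dtree)


@dataclass
class AncestralStates:
    """Per-internal-node trait values, ordered by preorder node index."""

    node_indices: np.ndarray  # internal node preorder indices
    node_ids: list[str]
    values: np.ndarray  # (n_internal, p)
    method: str = "scp-weighted"

    def as_dict(self) -> dict[str, np.ndarray]:
        return {nid: self.values[i] for i, nid in enumerate(self.node_ids)}


class ScpSolver:
    """Prefactorized squared-change-parsimony solver for one tree.

    Minimizes sum over edges of (state change)^2 / branch length (weighted)
    or the unweighted sum of squared changes, exactly, as a sparse linear
    system; the factorization depends only on the tree, so repeated solves
    with different tip data (e.g. across null simulations) are cheap.
    """

    def __init__(self, tree: TimeTree, weighted: bool = True):
        self.tree = tree
        self.weighted = weighted
        blen = tree.effective_blen()
        internal = np.flatnonzero(~tree.is_tip)
        self.internal = internal
        pos = {int(n): j for j, n in enumerate(internal)}
        ni = len(internal)
        diag = np.zeros(ni)
        rows, cols, vals = [], [], []
        # tip contribution matrix: rhs = T @ tip_values
        trows, tcols, tvals = [], [], []
        tip_pos = {int(t): j for j, t in enumerate(tree.tip_indices)}
        for child in range(1, tree.n_nodes):
            par = tree.parent[child]
            w = 1.0 / blen[child] if weighted else 1.0
            jp = pos[int(par)]
            diag[jp] += w
            if tree.is_tip[child]:
                trows.append(jp)
                tcols.append(tip_pos[int(child)])
                tvals.append(w)
            else:
                jc = pos[int(child)]
                diag[jc] += w
                rows.append(jp)
                cols.append(jc)
                vals.append(-w)
                rows.append(jc)
                cols.append(jp)
                vals.append(-w)
        rows_all = np.concatenate([rows, np.arange(ni)]).astype(int)
        cols_all = np.concatenate([cols, np.arange(ni)]).astype(int)
        vals_all = np.concatenate([vals, diag])
        A = sp.coo_matrix((vals_all, (rows_all, cols_all)), shape=(ni, ni)).tocsc()
        self._T = sp.coo_matrix((tvals, (trows, tcols)),
                                shape=(ni, tree.n_tips)).tocsr()
        self._lu = spla.splu(A)

    def solve(self, tip_values: np.ndarray) -> np.ndarray:
        """Internal-node states for ``(n_tips, p)`` tip values (tip order
        = ``tree.tip_labels``)."""
        tv = np.atleast_2d(np.asarray(tip_values, dtype=float))
        if tv.shape[0] != self.tree.n_tips:
            tv = tv.T
        rhs = self._T @ tv
        return self._lu.solve(rhs)


def _tip_matrix(tree: TimeTree, tip_values) -> np.ndarray:
    """Coerce a taxon->vector mapping or array into tip-order (n_tips, p)."""
    if isinstance(tip_values, Mapping):
        missing = [t for t in tree.tip_labels if t not in tip_values]
        if missing:
            raise KeyError(f"missing tip values for: {missing}")
        rows = [np.atleast_1d(np.asarray(tip_values[t], dtype=float))
                for t in tree.tip_labels]
        return np.vstack([r[None, :] if r.ndim == 1 else r for r in rows])
    arr = np.asarray(tip_values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != tree.n_tips:
        raise ValueError(
            f"tip value rows ({arr.shape[0]}) != number of tips ({tree.n_tips})"
        )
    return arr


def ancestral_scp(tree: TimeTree, tip_values, weighted: bool = True) -> AncestralStates:
    """Squared-change-parsimony ancestral states, each trait independent.

    ``tip_values`` maps taxon -> trait vector (or is an array in
    ``tree.tip_labels`` order). Returns exact minimizers of the
    (branch-length-weighted) sum of squared changes.
    """
    tv = _tip_matrix(tree, tip_values)
    solver = ScpSolver(tree, weighted=weighted)
    values = solver.solve(tv)
    internal = solver.internal
    return AncestralStates(
        node_indices=internal,
        node_ids=[tree.labels[i] for i in internal],
        values=values,
        method="scp-weighted" if weighted else "scp-unweighted",
    )


@dataclass
class PhylomorphospaceLayout:
    """Tree drawn into the (PC1, PC2) plane.

    ``points`` holds one row per node in preorder (tips at their empirical
    scores, internal nodes at squared-change-parsimony estimates); ``edges``
    are (parent, child) preorder index pairs.
    """

    tree: TimeTree
    points: np.ndarray  # (n_nodes, 2)
    edges: np.ndarray  # (n_nodes - 1, 2) parent, child indices
    node_ids: list[str]
    node_types: list[str]  # "tip" | "node"

    @property
    def tip_points(self) -> np.ndarray:
        return self.points[self.tree.tip_indices]

    @property
    def node_points(self) -> np.ndarray:
        return self.points[~self.tree.is_tip]

    def to_frames(self):
        import pandas as pd

        pts = pd.DataFrame(
            {"id": self.node_ids, "type": self.node_types,
             "PC1": self.points[:, 0], "PC2": self.points[:, 1]}
        )
        edges = pd.DataFrame(
            {"parent": [self.node_ids[p] for p, _ in self.edges],
             "child": [self.node_ids[c] for _, c in self.edges]}
        )
        return pts, edges


def phylomorphospace(tree: TimeTree, ms_or_scores, taxa: Sequence[str] | None = None,
                     weighted: bool = True) -> PhylomorphospaceLayout:
    """Phylomorphospace layout: empirical tip scores plus SCP ancestors.

    ``ms_or_scores`` is a :class:`~opershape.morphospace.Morphospace` (tip
    scores looked up by taxon) or an ``(n_tips, 2)`` array in tree tip
    order.
    """
    from .morphospace import Morphospace

    if isinstance(ms_or_scores, Morphospace):
        tips = ms_or_scores.scores_for(tree.tip_labels, n_components=2)
    else:
        tips = np.asarray(ms_or_scores, dtype=float)[:, :2]
        if taxa is not None:
            order = {t: i for i, t in enumerate(taxa)}
            tips = tips[[order[t] for t in tree.tip_labels]]
    anc = ancestral_scp(tree, tips, weighted=weighted)
    points = np.zeros((tree.n_nodes, 2))
    points[tree.tip_indices] = tips
    points[anc.node_indices] = anc.values
    edges = np.array([[tree.parent[i], i] for i in range(1, tree.n_nodes)])
    node_ids = list(tree.labels)
    node_types = ["tip" if t else "node" for t in tree.is_tip]
    return PhylomorphospaceLayout(tree=tree, points=points, edges=edges,
                                  node_ids=node_ids, node_types=node_types)


def _rate_factor(rate, p: int) -> np.ndarray:
    """Matrix square root factor L with L @ L.T = rate (PSD checked)."""
    if np.isscalar(rate):
        if rate < 0:
            raise ValueError("negative rate")
        return np.eye(p) * np.sqrt(rate)
    R = np.asarray(rate, dtype=float)
    if R.shape != (p, p) or not np.allclose(R, R.T):
        raise ValueError("rate matrix must be symmetric (p, p)")
    eigval, eigvec = np.linalg.eigh(R)
    if eigval.min() < -1e-10 * max(abs(eigval.max()), 1.0):
        raise ValueError("rate matrix is not positive semi-definite")
    return eigvec @ np.diag(np.sqrt(np.clip(eigval, 0, None)))


def bm_simulate(tree: TimeTree, rate, root_state, n_sims: int = 1,
                seed: int | None = None, return_nodes: bool = False):
    """Simulate Brownian motion along the tree.

    Each branch adds a Gaussian increment with covariance
    ``rate * branch_length``; ``rate`` is a scalar (shared by independent
    traits) or a full (p, p) trait covariance. Returns tip values of shape
    ``(n_sims, n_tips, p)`` (tip order = ``tree.tip_labels``); with
    ``return_nodes`` also all-node values ``(n_sims, n_nodes, p)``.
    Bit-reproducible for a fixed seed.
    """
    root = np.atleast_1d(np.asarray(root_state, dtype=float))
    p = root.shape[0]
    L = _rate_factor(rate, p)
    rng = np.random.default_rng(seed)
    states = np.empty((n_sims, tree.n_nodes, p))
    states[:, 0, :] = root
    increments = rng.standard_normal((n_sims, tree.n_nodes, p))
    sqrt_bl = np.sqrt(np.clip(tree.blen, 0, None))
    # preorder guarantees parents precede children
    for i in range(1, tree.n_nodes):
        states[:, i, :] = states[:, tree.parent[i], :] + sqrt_bl[i] * (
            increments[:, i, :] @ L.T
        )
    tips = states[:, tree.tip_indices, :]
    if return_nodes:
        return tips, states
    return tips
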