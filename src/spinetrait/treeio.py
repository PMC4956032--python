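"""Rooted phylogenies: reading, validation, pruning, and the Brownian-motion
phylogenetic covariance matrix.

Trees are stored in a flat array representation (parent pointers + branch
lengths) that the numerical modules consume directly; Newick/Nexus parsing and
writing are delegated to dendropy.  All trees are rooted; the root carries no
branch length (a root edge present in the input is ignored with a warning,
since the BM covariance is defined from the root).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger("spinetrait.treeio")

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "TreeError",
    "TreeParseError",
    "TaxonMismatchError",
    "read_tree",
    "write_tree",
    "prune_to_taxa",
    "vcv_matrix",
    "match_taxa",
]


class TreeError(ValueError):
    """Invalid tree structure or content."""


class TreeParseError(TreeError):
    """Malformed Newick/Nexus input."""


class TaxonMismatchError(TreeError):
    """Tree tips and trait-table taxa do not reconcile."""


def normalize_label(label: str) -> str:
    """Canonical form for taxon-name matching: trimmed, underscores and
    whitespace runs collapsed to single spaces."""
    return re.sub(r"[\s_]+", " ", label.strip())


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, in parent-pointer form.

    Nodes are indexed 0..n_nodes-1 with tips occupying 0..n_tips-1 (in the
    order the tips appeared in the source tree).  ``parent[i]`` is the index
    of node i's parent (-1 for the root); ``lengths[i]`` is the length of the
    branch above node i (0.0 and unused for the root).
    """

    parent: np.ndarray
    lengths: np.ndarray
    tip_labels: list[str]
    root: int
    _children: list[list[int]] | None = field(default=None, repr=False)
    _postorder: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        self.validate()

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    @property
    def postorder(self) -> np.ndarray:
        """Node indices in postorder (children before parents, root last)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = np.asarray(order[::-1], dtype=np.int64)
        return self._postorder

    def validate(self) -> None:
        n = self.n_nodes
        if not (0 <= self.root < n) or self.parent[self.root] != -1:
            raise TreeError("root index invalid or root has a parent")
        if np.sum(self.parent == -1) != 1:
            raise TreeError("tree must have exactly one root")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dupes = sorted(
                {t for t in self.tip_labels if self.tip_labels.count(t) > 1}
            )
            raise TreeError(f"duplicate tip labels: {dupes}")
        nonroot = np.arange(n) != self.root
        if np.any(self.lengths[nonroot] < 0) or not np.all(
            np.isfinite(self.lengths[nonroot])
        ):
            raise TreeError("branch lengths must be finite and >= 0")
        # connectivity/acyclicity: every node must reach the root
        for i in range(n):
            seen = 0
            j = i
            while j != self.root:
                j = int(self.parent[j])
                seen += 1
                if j < 0 or seen > n:
                    raise TreeError("tree is disconnected or cyclic")

    def copy_with_lengths(self, lengths: np.ndarray) -> "Phylogeny":
        """Same topology with replaced branch lengths (used by the kappa
        transform)."""
        return Phylogeny(
            self.parent.copy(), np.asarray(lengths, float), list(self.tip_labels), self.root
        )

    # ------------------------------------------------------------------
    # metrics
    # ------------------------------------------------------------------
    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for v in self.postorder[::-1]:  # preorder
            if v != self.root:
                d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    def tip_depths(self) -> np.ndarray:
        return self.depths()[: self.n_tips]

    def tip_distance_matrix(self) -> np.ndarray:
        """Pairwise patristic distances between tips."""
        C = vcv_matrix(self).matrix
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2.0 * C

    def clade_tips(self, node: int) -> list[int]:
        """Tip indices descending from (or equal to) ``node``."""
        out: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(v)
            stack.extend(self.children[v])
        return sorted(out)

    def node_fingerprint(self, node: int) -> str:
        """Stable identifier for an internal node: sorted descendant tips."""
        return "|".join(sorted(self.tip_labels[i] for i in self.clade_tips(node)))

    def tip_edge_incidence(self) -> np.ndarray:
        """Dense (n_tips x n_nodes) indicator: A[i, v] = 1 iff the branch
        above node v lies on the root-to-tip-i path.  The root column is
        always zero.  C = A diag(lengths) A' is the BM covariance."""
        A = np.zeros((self.n_tips, self.n_nodes))
        for i in range(self.n_tips):
            v = i
            while v != self.root:
                A[i, v] = 1.0
                v = int(self.parent[v])
        return A

    def node_edge_incidence(self) -> np.ndarray:
        """As ``tip_edge_incidence`` but with one row per node (root-to-node
        paths), used for ancestral-state covariances."""
        A = np.zeros((self.n_nodes, self.n_nodes))
        for i in range(self.n_nodes):
            v = i
            while v != self.root:
                A[i, v] = 1.0
                v = int(self.parent[v])
        return A


@dataclass
class PhyloCovariance:
    """BM covariance among tips: C[i, j] = shared root-to-MRCA path length.

    ``transform`` records the Pagel parameters applied ("raw" when none)."""

    taxa: list[str]
    matrix: np.ndarray
    transform: dict | str = "raw"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.taxa):
            raise TreeError("covariance matrix shape does not match taxa")
        if not np.allclose(m, m.T, atol=1e-12):
            raise TreeError("covariance matrix must be symmetric")


# ----------------------------------------------------------------------
# dendropy bridge
# ----------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    seed = dtree.seed_node
    if seed.edge.length is not None:
        logger.warning(
            "input tree has a root edge of length %s; ignored (BM covariance "
            "is defined from the root)",
            seed.edge.length,
        )
    leaves = [nd for nd in dtree.leaf_node_iter()]
    labels = []
    for nd in leaves:
        lbl = nd.taxon.label if nd.taxon is not None else nd.label
        if lbl is None:
            raise TreeParseError("tip without a label")
        labels.append(str(lbl))
    if len(set(labels)) != len(labels):
        dupes = sorted({t for t in labels if labels.count(t) > 1})
        raise TreeParseError(f"duplicate tip labels: {dupes}")
    index = {id(nd): i for i, nd in enumerate(leaves)}
    internals = [
        nd for nd in dtree.postorder_node_iter() if not nd.is_leaf()
    ]
    for nd in internals:
        index[id(nd)] = len(index)
    n = len(index)
    parent = np.full(n, -1, dtype=np.int64)
    lengths = np.zeros(n)
    for nd in dtree.preorder_node_iter():
        i = index[id(nd)]
        if nd is seed:
            continue
        parent[i] = index[id(nd.parent_node)]
        if nd.edge.length is None:
            raise TreeParseError(
                f"branch length missing on the edge above "
                f"{'tip ' + labels[i] if i < len(labels) else 'an internal node'}; "
                "explicit lengths are required (use grafen=True to assign "
                "Grafen-style depths)"
            )
        lengths[i] = float(nd.edge.length)
    return Phylogeny(parent, lengths, labels, index[id(seed)])


def _to_dendropy(tree: Phylogeny) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    nodes = [dendropy.Node() for _ in range(tree.n_nodes)]
    for i, lbl in enumerate(tree.tip_labels):
        nodes[i].taxon = taxa.new_taxon(label=lbl)
    for i, p in enumerate(tree.parent):
        if p >= 0:
            nodes[p].add_child(nodes[i])
            nodes[i].edge.length = float(tree.lengths[i])
    dtree = dendropy.Tree(taxon_namespace=taxa)
    dtree.seed_node = nodes[tree.root]
    dtree.is_rooted = True
    return dtree


def read_tree(text: str, dialect: str = "newick", grafen: bool = False) -> Phylogeny:
    """Parse a rooted tree from a Newick or Nexus string.

    Branch lengths are required on all non-root edges unless ``grafen=True``,
    in which case Grafen-style depths (clade-size based, scaled to unit root
    depth) are assigned to the topology and logged.  Nexus TRANSLATE blocks
    and quoted labels are supported via dendropy.
    """
    if dialect not in ("newick", "nexus"):
        raise ValueError(f"unknown tree dialect {dialect!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=dialect,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeParseError(f"could not parse {dialect} tree: {exc}") from exc
    if grafen:
        _assign_grafen(dtree)
        logger.info("assigned Grafen-style branch lengths (unit root depth)")
    return _from_dendropy(dtree)


def _assign_grafen(dtree: dendropy.Tree) -> None:
    """Grafen (1989)-style lengths: node height = (clade tip count - 1),
    normalized so root-to-tip depth is 1 on every path."""
    counts: dict[int, int] = {}
    for nd in dtree.postorder_node_iter():
        counts[id(nd)] = 1 if nd.is_leaf() else sum(
            counts[id(c)] for c in nd.child_nodes()
        )
    total = counts[id(dtree.seed_node)]
    denom = max(total - 1, 1)
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is None:
            nd.edge.length = None
            continue
        h_parent = (counts[id(nd.parent_node)] - 1) / denom
        h_child = (counts[id(nd)] - 1) / denom
        nd.edge.length = h_parent - h_child


def write_tree(tree: Phylogeny) -> str:
    """Serialize as strict Newick with 12 significant digits."""
    dtree = _to_dendropy(tree)
    s = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        preserve_spaces=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    )
    return s.strip() + "\n"


# ----------------------------------------------------------------------
# pruning
# ----------------------------------------------------------------------

def prune_to_taxa(
    tree: Phylogeny, keep: set[str] | list[str], keep_stem: bool = True
) -> Phylogeny:
    """Induced subtree on ``keep``: unsampled tips removed and degree-2
    internal nodes collapsed with branch lengths summed.

    With ``keep_stem=True`` (default) the original root position is retained,
    so the BM covariance of the pruned tree equals the corresponding submatrix
    of the full tree's covariance; if the kept taxa form a proper subclade the
    result then has a unifurcate root.  With ``keep_stem=False`` the MRCA of
    the kept taxa becomes the root and the stem path is discarded (pairwise
    tip distances are preserved either way).
    """
    keep = set(keep)
    known = set(tree.tip_labels)
    unknown = sorted(keep - known)
    if unknown:
        raise TaxonMismatchError(f"labels not in tree: {unknown}")
    if not keep:
        raise TreeError("cannot prune to an empty taxon set")

    # bottom-up reduction: each node maps to a list of (subtree, stem-length)
    # where subtree is a nested (label | list) structure
    def reduce(v: int) -> list:
        if v < tree.n_tips:
            if tree.tip_labels[v] in keep:
                return [(tree.tip_labels[v], tree.lengths[v])]
            return []
        kept = []
        for c in tree.children[v]:
            sub = reduce(c)
            if len(sub) == 1:
                # pass-through: absorb this node's edge into the child's stem
                (node_repr, ln) = sub[0]
                kept.append((node_repr, ln))
            elif len(sub) >= 2:
                kept.append((sub, 0.0))
        # add the edge above v to each surviving lineage's stem
        ln_v = 0.0 if v == tree.root else float(tree.lengths[v])
        if len(kept) == 1:
            return [(kept[0][0], kept[0][1] + ln_v)]
        if len(kept) >= 2:
            return [(kept, ln_v)]
        return []

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, tree.n_nodes * 2 + 100))
    try:
        result = reduce(tree.root)
    finally:
        sys.setrecursionlimit(old)
    (structure, stem) = result[0]

    # rebuild arrays
    tips: list[str] = []
    parent: list[int] = []
    lengths: list[float] = []

    def count(struct) -> int:
        if isinstance(struct, str):
            return 1
        return sum(count(s) for s, _ in struct)

    n_tips_new = count(structure)
    tip_cursor = [0]
    internal_cursor = [n_tips_new]
    n_total = _count_nodes(structure, keep_stem and not isinstance(structure, str) and stem > 0)

    parent_arr = np.full(n_total, -1, dtype=np.int64)
    length_arr = np.zeros(n_total)
    labels: list[str] = [""] * n_tips_new

    def build(struct, stem_len: float, parent_idx: int) -> int:
        if isinstance(struct, str):
            i = tip_cursor[0]
            tip_cursor[0] += 1
            labels[i] = struct
            parent_arr[i] = parent_idx
            length_arr[i] = stem_len
            return i
        i = internal_cursor[0]
        internal_cursor[0] += 1
        parent_arr[i] = parent_idx
        length_arr[i] = stem_len
        for sub, ln in struct:
            build(sub, ln, i)
        return i

    if isinstance(structure, str):
        # single tip kept: degenerate two-node tree (root + tip with stem)
        if keep_stem:
            return Phylogeny(
                np.array([1, -1]), np.array([stem, 0.0]), [structure], 1
            )
        raise TreeError("pruning to a single taxon requires keep_stem=True")

    if keep_stem and stem > 0:
        # unifurcate root above the reduced subtree
        root_idx = n_total - 1
        parent_arr[root_idx] = -1
        sub_root = build(structure, stem, root_idx)
        return Phylogeny(parent_arr, length_arr, labels, root_idx)
    root_idx = build(structure, 0.0, -1)
    return Phylogeny(parent_arr, length_arr, labels, root_idx)


def _count_nodes(struct, extra_root: bool) -> int:
    def rec(s) -> int:
        if isinstance(s, str):
            return 1
        return 1 + sum(rec(c) for c, _ in s)

    return rec(struct) + (1 if extra_root else 0)


# ----------------------------------------------------------------------
# BM covariance
# ----------------------------------------------------------------------

def vcv_matrix(tree: Phylogeny) -> PhyloCovariance:
    """Brownian-motion covariance: C[i, j] = path length from the root to
    MRCA(i, j); C[i, i] = root-to-tip depth."""
    n = tree.n_tips
    C = np.zeros((n, n))
    depths = tree.depths()
    np.fill_diagonal(C, depths[:n])
    # for each internal node, pairs of tips in distinct child subtrees share
    # exactly the path root->node
    for v in tree.postorder:
        if v < n:
            continue
        groups = [tree.clade_tips(c) for c in tree.children[v]]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                C[np.ix_(groups[a], groups[b])] = depths[v]
                C[np.ix_(groups[b], groups[a])] = depths[v]
    return PhyloCovariance(list(tree.tip_labels), C, "raw")


# ----------------------------------------------------------------------
# taxon reconciliation
# ----------------------------------------------------------------------

def match_taxa(
    tree: Phylogeny, taxa: list[str], prune: bool = False
) -> tuple[Phylogeny, list[str]]:
    """Reconcile tree tips with trait-table taxa by normalized exact match.

    Returns the (possibly pruned) tree and the trait-table taxa present in
    it, in table order.  A mismatch raises with a side-by-side report unless
    ``prune=True``, which prunes both sides to the intersection (logged).
    """
    tree_norm = {normalize_label(t): t for t in tree.tip_labels}
    table_norm = {normalize_label(t): t for t in taxa}
    only_tree = sorted(set(tree_norm) - set(table_norm))
    only_table = sorted(set(table_norm) - set(tree_norm))
    if (only_tree or only_table) and not prune:
        lines = ["tree tips and trait taxa do not match:"]
        lines += [f"  tree only : {tree_norm[t]}" for t in only_tree]
        lines += [f"  table only: {table_norm[t]}" for t in only_table]
        lines.append("(pass prune=True / --prune to use the intersection)")
        raise TaxonMismatchError("\n".join(lines))
    shared = set(tree_norm) & set(table_norm)
    if len(shared) < 3:
        raise TaxonMismatchError("fewer than 3 shared taxa between tree and table")
    if only_tree or only_table:
        logger.info(
            "pruning to %d shared taxa (%d tree-only, %d table-only dropped)",
            len(shared), len(only_tree), len(only_table),
        )
    pruned = (
        prune_to_taxa(tree, {tree_norm[t] for t in shared})
        if only_tree
        else tree
    )
    kept_table = [table_norm[normalize_label(t)] for t in taxa if normalize_label(t) in shared]
    return pruned, kept_table
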