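"""Guide trees: Newick I/O, overlap-distance clustering, random topologies.

The optimizer only ever removes sequence sets that form one side of a guide
tree bipartition, so the guide tree defines the search space.  Any rooted
hierarchy works: a phylogeny read from Newick, an agglomerative clustering
of the sequences by *overlap distance* — for two aligned sequences over
``n`` columns, ``n`` minus the number of columns where both are resolved —
or a random topology (useful as a sensitivity baseline).

Trees are plain linked :class:`TreeNode` objects (polytomies allowed);
branch lengths are carried through I/O but ignored by the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

from .errors import (
    ConfigurationError,
    DomainError,
    FormatError,
    IdentityError,
)
from .msa_io import PresenceMatrix

__all__ = [
    "TreeNode",
    "GuideTree",
    "DistanceMatrix",
    "LINKAGES",
    "overlap_distance",
    "distance_matrix",
    "hierarchical_cluster",
    "read_newick",
    "write_newick",
    "root_if_needed",
    "random_tree",
    "prune_leaves",
]

LINKAGES = ("complete", "single", "average", "median", "centroid", "ward")


class TreeNode:
    """One node of a rooted guide tree.

    ``leaf_name`` is set for leaves only.  ``id`` is assigned by
    :meth:`GuideTree.reindex` (preorder numbering) and is stable under
    pruning, which keeps candidate ranking deterministic.
    """

    __slots__ = ("id", "children", "parent", "leaf_name", "length", "label")

    def __init__(self, leaf_name: str | None = None, length: float | None = None,
                 label: str | None = None) -> None:
        self.id: int = -1
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.leaf_name = leaf_name
        self.length = length
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "TreeNode") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"leaf {self.leaf_name!r}" if self.is_leaf else f"{len(self.children)} children"
        return f"<TreeNode id={self.id} {kind}>"


class GuideTree:
    """A rooted tree over alignment sequence names (leaves)."""

    def __init__(self, root: TreeNode, reindex: bool = True) -> None:
        self.root = root
        if reindex:
            self.reindex()
        self._validate()

    def _validate(self) -> None:
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise IdentityError("duplicate leaf names in guide tree")

    def reindex(self) -> None:
        """Assign preorder ids; called after construction, not after pruning."""
        for i, node in enumerate(self.preorder()):
            node.id = i

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.leaf_name for n in self.leaves()]  # type: ignore[misc]

    @property
    def leaf_count(self) -> int:
        return len(self.leaves())

    def find(self, node_id: int) -> TreeNode | None:
        for node in self.preorder():
            if node.id == node_id:
                return node
        return None

    def copy(self) -> "GuideTree":
        """Deep copy preserving node ids."""
        mapping: dict[int, TreeNode] = {}
        for node in self.preorder():
            clone = TreeNode(leaf_name=node.leaf_name, length=node.length,
                             label=node.label)
            clone.id = node.id
            mapping[id(node)] = clone
            if node.parent is not None:
                mapping[id(node.parent)].add_child(clone)
        return GuideTree(mapping[id(self.root)], reindex=False)

    def newick(self, include_lengths: bool = True) -> str:
        """Serialize to a Newick string (iterative; safe for deep trees)."""
        parts: dict[int, str] = {}
        for node in self.postorder():
            if node.is_leaf:
                body = _quote_newick_label(node.leaf_name or "")
            else:
                inner = ",".join(parts.pop(id(c)) for c in node.children)
                label = _quote_newick_label(node.label) if node.label else ""
                body = f"({inner}){label}"
            if include_lengths and node.length is not None:
                body += f":{node.length:g}"
            parts[id(node)] = body
        return parts[id(self.root)] + ";"


def _quote_newick_label(label: str) -> str:
    if label and any(c in label for c in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Overlap distance and agglomerative clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise overlap distances.

    The diagonal holds the number of missing positions of each sequence
    (zero for a fully resolved sequence), consistent with applying the
    overlap distance to a sequence against itself.
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        v = np.asarray(self.values, dtype=np.int64)
        if v.shape != (len(self.names), len(self.names)):
            raise DomainError("distance matrix shape does not match names")
        if (v != v.T).any() or (v < 0).any():
            raise DomainError("distance matrix must be symmetric and non-negative")
        object.__setattr__(self, "values", v)


def overlap_distance(pm: PresenceMatrix, seq_a: str, seq_b: str) -> int:
    """Alignment length minus the number of columns where both are resolved."""
    a = pm.row(seq_a)
    b = pm.row(seq_b)
    return int(pm.n_cols - int(np.count_nonzero(a & b)))


def distance_matrix(pm: PresenceMatrix) -> DistanceMatrix:
    """All pairwise overlap distances, computed as n - B @ B.T on indicators."""
    if len(pm.names) < 2:
        raise DomainError("need at least 2 sequences for a distance matrix")
    b = pm.values
    overlap = b @ b.T
    return DistanceMatrix(names=pm.names, values=pm.n_cols - overlap)


# Lance-Williams coefficients (a_i, a_j, beta, gamma) as functions of the
# cluster sizes (ni, nj, nk).  median/centroid/ward operate on squared
# distances, following the standard formulation.
def _lw_coefficients(linkage: str, ni: int, nj: int, nk: int):
    if linkage == "single":
        return 0.5, 0.5, 0.0, -0.5
    if linkage == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if linkage == "average":
        s = ni + nj
        return ni / s, nj / s, 0.0, 0.0
    if linkage == "median":
        return 0.5, 0.5, -0.25, 0.0
    if linkage == "centroid":
        s = ni + nj
        return ni / s, nj / s, -(ni * nj) / (s * s), 0.0
    if linkage == "ward":
        s = ni + nj + nk
        return (ni + nk) / s, (nj + nk) / s, -nk / s, 0.0
    raise ConfigurationError(
        f"unknown linkage {linkage!r}; choose one of {', '.join(LINKAGES)}"
    )


def hierarchical_cluster(dm: DistanceMatrix, linkage: str = "median",
                         max_sequences: int = 10_000) -> GuideTree:
    """Agglomerative clustering of the overlap-distance matrix.

    Classic O(n^3) agglomeration: repeatedly merge the two clusters at
    minimum distance, updating distances with the Lance-Williams recurrence
    for the chosen linkage (median, centroid and Ward update squared
    distances).  Ties on the minimum merge the lexicographically smallest
    pair of cluster indices, which makes the topology deterministic.

    Above ``max_sequences`` leaves the call is refused; build the guide tree
    with an external fast phylogeny program (e.g. fasttree) instead and load
    it with :func:`read_newick`.
    """
    if linkage not in LINKAGES:
        raise ConfigurationError(
            f"unknown linkage {linkage!r}; choose one of {', '.join(LINKAGES)}"
        )
    n = len(dm.names)
    if n > max_sequences:
        raise DomainError(
            f"{n} sequences exceeds the clustering limit of {max_sequences}; "
            "O(n^3) agglomeration is impractical here - supply an external "
            "guide tree (e.g. from fasttree) instead"
        )
    d = dm.values.astype(np.float64).copy()
    if linkage in ("median", "centroid", "ward"):
        d = d**2
    np.fill_diagonal(d, np.inf)

    nodes: list[TreeNode | None] = [TreeNode(leaf_name=name) for name in dm.names]
    sizes = np.ones(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    work = d.copy()
    work[:, ~active] = np.inf

    last: TreeNode | None = nodes[0]
    for _ in range(n - 1):
        # argmin over the row-major flattened matrix lands on the
        # lexicographically smallest (i, j) among tied minima
        flat = np.argmin(work)
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        parent = TreeNode()
        parent.add_child(nodes[i])  # type: ignore[arg-type]
        parent.add_child(nodes[j])  # type: ignore[arg-type]
        nodes[i], nodes[j] = parent, None
        last = parent
        ni, nj = int(sizes[i]), int(sizes[j])
        for k in np.flatnonzero(active):
            if k == i or k == j:
                continue
            ai, aj, beta, gamma = _lw_coefficients(linkage, ni, nj, int(sizes[k]))
            dik, djk, dij = work[i, k], work[j, k], work[i, j]
            new = ai * dik + aj * djk + beta * dij + gamma * abs(dik - djk)
            work[i, k] = work[k, i] = new
        sizes[i] = ni + nj
        active[j] = False
        work[j, :] = np.inf
        work[:, j] = np.inf
    assert last is not None
    return GuideTree(last)


# ---------------------------------------------------------------------------
# Newick I/O and tree utilities
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> GuideTree:
    mapping: dict[int, TreeNode] = {}
    root = None
    for dnode in dtree.preorder_node_iter():
        name = dnode.taxon.label if dnode.taxon is not None else None
        label = dnode.label if dnode.label else None
        node = TreeNode(leaf_name=name if dnode.is_leaf() else None,
                        length=dnode.edge.length, label=label)
        mapping[id(dnode)] = node
        if dnode.parent_node is None:
            root = node
        else:
            mapping[id(dnode.parent_node)].add_child(node)
    assert root is not None
    return GuideTree(root)


def read_newick(path: str | Path) -> GuideTree:
    """Read a Newick tree; polytomies and trifurcating (unrooted) roots accepted."""
    path = Path(path)
    try:
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as newick: {exc}") from exc
    tree = _from_dendropy(dtree)
    if tree.leaf_count < 1:
        raise FormatError(f"newick tree in {path} has no leaves")
    return root_if_needed(tree)


def write_newick(tree: GuideTree, path: str | Path) -> None:
    """Write the tree as Newick, preserving branch lengths where present."""
    Path(path).write_text(tree.newick() + "\n")


def root_if_needed(tree: GuideTree) -> GuideTree:
    """Ensure the root is an inner node (collapsing any unary root chain).

    A trifurcating root from an unrooted Newick file is kept as a rooted
    polytomy at that node; the downstream recursions support
    multifurcations directly.
    """
    root = tree.root
    while len(root.children) == 1:
        child = root.children[0]
        if child.length is not None and root.length is not None:
            child.length += root.length
        child.parent = None
        root = child
    if root is not tree.root:
        return GuideTree(root)
    return tree


def random_tree(names: Sequence[str], seed: int) -> GuideTree:
    """Random binary topology over ``names``, reproducible from ``seed``.

    Built by repeated random joins of two remaining lineages (a labelled
    coalescent), so every rooted binary topology has positive probability.
    """
    names = list(names)
    if len(names) < 2:
        raise DomainError("need at least 2 names for a random tree")
    rng = np.random.default_rng(seed)
    pool: list[TreeNode] = [TreeNode(leaf_name=n) for n in names]
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        parent = TreeNode()
        parent.add_child(pool[i])
        parent.add_child(pool[j])
        pool[j:j + 1] = []
        pool[i] = parent
    return GuideTree(pool[0])


def prune_leaves(tree: GuideTree, names: Iterable[str]) -> GuideTree:
    """Remove the named leaves in place, suppressing unary nodes created.

    Branch lengths of collapsed unary nodes are summed onto the surviving
    child.  Node ids of surviving nodes are preserved.
    """
    doomed = set(names)
    unknown = doomed - set(tree.leaf_names())
    if unknown:
        raise IdentityError(f"cannot prune unknown leaves: {sorted(unknown)}")
    if len(doomed) >= tree.leaf_count:
        raise DomainError("pruning would remove every leaf")
    for leaf in list(tree.leaves()):
        if leaf.leaf_name not in doomed:
            continue
        parent = leaf.parent
        if parent is None:
            raise DomainError("cannot prune the root leaf")
        parent.remove_child(leaf)
        node = parent
        while node is not None and not node.is_leaf and len(node.children) == 1:
            child = node.children[0]
            if child.length is not None and node.length is not None:
                child.length += node.length
            grand = node.parent
            if grand is None:
                child.parent = None
                tree.root = child
            else:
                grand.children[grand.children.index(node)] = child
                child.parent = grand
            node = grand
    return tree
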