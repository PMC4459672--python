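"""Dynamic-programming partition scores on the guide tree.

Every branch of a rooted guide tree splits the sequences into a *down* set
(the leaves of the subtree below the branch) and an *up* set (the
complement, containing the root).  For each node ``N`` we store two integer
arrays over alignment columns:

* ``down(N)[i]`` — the number of resolved characters at column ``i`` among
  the down-set sequences (a leaf's array is its presence-matrix row; an
  inner node's array is the element-wise sum of its children's arrays,
  filled in one post-order traversal);
* ``up(N)[i]`` — the same count over the complement, filled in one
  pre-order traversal from the identity
  ``up(N) = up(F) + sum(down(brothers of N)) = up(F) + down(F) - down(N)``.

With the arrays in hand, the number of columns whose pooled resolved
fraction meets a coverage threshold ``t`` is a single vector comparison per
partition, optionally pooling a set of protected *reference* sequences that
live outside the tree.  At ``t = 1.0`` the counts reduce to the boolean
"no missing character in the set" rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np

from .errors import DomainError, IdentityError, StateError
from .guide_tree import GuideTree
from .msa_io import PresenceMatrix

__all__ = [
    "NodeScores",
    "ReferenceSet",
    "Side",
    "CandidatePartition",
    "compute_down",
    "compute_up",
    "site_count",
    "enumerate_candidates",
]


class Side(str, Enum):
    """Which side of the bipartition is kept."""

    keep_down = "keep_down"
    keep_up = "keep_up"


@dataclass
class NodeScores:
    """Per-node down/up count arrays, keyed by node id.

    ``down_visits``/``up_visits`` count how often each node was touched by
    the traversals; both stay at one visit per node per full pass, which is
    what makes the two-traversal scheme linear in tree size.
    """

    n_cols: int
    down: dict[int, np.ndarray] = field(default_factory=dict)
    up: dict[int, np.ndarray] = field(default_factory=dict)
    n_down: dict[int, int] = field(default_factory=dict)
    n_up: dict[int, int] = field(default_factory=dict)
    leaf_sets: dict[int, frozenset[str]] = field(default_factory=dict)
    down_visits: dict[int, int] = field(default_factory=dict)
    up_visits: dict[int, int] = field(default_factory=dict)

    def drop(self, node_ids: Iterable[int]) -> None:
        """Forget state for nodes no longer in the tree."""
        for nid in node_ids:
            for d in (self.down, self.up, self.n_down, self.n_up,
                      self.leaf_sets, self.down_visits, self.up_visits):
                d.pop(nid, None)


@dataclass(frozen=True)
class ReferenceSet:
    """Protected sequences pooled into every partition score.

    References are excluded from the guide tree (they can never be removed);
    their per-column resolved counts ``counts`` and their number ``n_ref``
    enter the coverage fraction of every candidate partition.
    """

    names: tuple[str, ...]
    counts: np.ndarray
    n_ref: int

    @classmethod
    def from_presence(cls, pm: PresenceMatrix, names: Iterable[str]) -> "ReferenceSet":
        names = tuple(names)
        if not names:
            raise DomainError("reference set must be non-empty")
        if len(set(names)) != len(names):
            raise IdentityError("duplicate reference names")
        idx = [pm.index(n) for n in names]
        counts = pm.values[idx].sum(axis=0)
        return cls(names=names, counts=counts, n_ref=len(names))


@dataclass(frozen=True)
class CandidatePartition:
    """One side of one tree bipartition, as a removal proposal.

    ``n_sites`` is the usable-column count of the kept set (references
    pooled in); ``n_chars`` is the total number of resolved characters in
    the kept data matrix, used as the last informative ranking key.
    """

    node_id: int
    side: Side
    kept_names: frozenset[str]
    removed_names: frozenset[str]
    n_removed: int
    n_sites: int
    n_chars: int


def compute_down(tree: GuideTree, pm: PresenceMatrix) -> NodeScores:
    """Post-order pass: fill every node's down array (leaves up to the root)."""
    scores = NodeScores(n_cols=pm.n_cols)
    for node in tree.postorder():
        scores.down_visits[node.id] = scores.down_visits.get(node.id, 0) + 1
        if node.is_leaf:
            if node.leaf_name is None:
                raise IdentityError(f"leaf node {node.id} has no name")
            scores.down[node.id] = pm.row(node.leaf_name).copy()
            scores.n_down[node.id] = 1
            scores.leaf_sets[node.id] = frozenset({node.leaf_name})
        else:
            acc = np.zeros(pm.n_cols, dtype=np.int64)
            n = 0
            names: set[str] = set()
            for child in node.children:
                acc += scores.down[child.id]
                n += scores.n_down[child.id]
                names |= scores.leaf_sets[child.id]
            scores.down[node.id] = acc
            scores.n_down[node.id] = n
            scores.leaf_sets[node.id] = frozenset(names)
    return scores


def compute_up(tree: GuideTree, scores: NodeScores) -> NodeScores:
    """Pre-order pass: fill every node's up array (root down to the leaves).

    The root's up array is all-zero (the complement of the whole tree is
    empty); for any other node ``N`` with father ``F``,
    ``up(N) = up(F) + down(F) - down(N)``, i.e. the father's complement plus
    all brother subtrees.  Requires :func:`compute_down` to have run.
    """
    if tree.root.id not in scores.down:
        raise StateError("compute_up called before compute_down")
    scores.up.clear()
    scores.n_up.clear()
    scores.up_visits.clear()
    for node in tree.preorder():
        scores.up_visits[node.id] = scores.up_visits.get(node.id, 0) + 1
        if node.parent is None:
            scores.up[node.id] = np.zeros(scores.n_cols, dtype=np.int64)
            scores.n_up[node.id] = 0
        else:
            f = node.parent.id
            scores.up[node.id] = scores.up[f] + scores.down[f] - scores.down[node.id]
            scores.n_up[node.id] = (
                scores.n_up[f] + scores.n_down[f] - scores.n_down[node.id]
            )
    return scores


def site_count(counts: np.ndarray, n_seq_set: int, t: float,
               refs: ReferenceSet | None = None) -> int:
    """Columns whose pooled resolved fraction meets threshold ``t`` (closed >=).

    With references, the fraction at column ``i`` is
    ``(counts[i] + R[i]) / (n_seq_set + n_ref)``.
    """
    if not 0.0 <= t <= 1.0:
        raise DomainError(f"threshold t must be in [0, 1], got {t}")
    num = np.asarray(counts, dtype=np.int64)
    den = int(n_seq_set)
    if refs is not None:
        num = num + refs.counts
        den += refs.n_ref
    if den < 1:
        raise DomainError("site_count over an empty sequence set")
    return int(np.count_nonzero(num / den >= t))


def enumerate_candidates(tree: GuideTree, scores: NodeScores,
                         refs: ReferenceSet | None, t: float,
                         current_sites: int) -> list[CandidatePartition]:
    """All improving bipartition sides of the current tree.

    Every non-root node contributes up to two candidates — keep the down
    set (remove the complement) or keep the up set (remove the subtree).
    Candidates whose site count does not strictly exceed ``current_sites``
    are discarded, as are keep-up candidates whose kept set would be empty.
    For a binary root the two root children yield complementary duplicates;
    both are emitted and the deterministic ranking keys resolve the tie.
    """
    root_id = tree.root.id
    if root_id not in scores.down or root_id not in scores.up:
        raise StateError("scores are not current for this tree")
    all_names = scores.leaf_sets[root_id]
    ref_names = frozenset(refs.names) if refs is not None else frozenset()
    ref_chars = int(refs.counts.sum()) if refs is not None else 0
    out: list[CandidatePartition] = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        nid = node.id
        down_set = scores.leaf_sets[nid]
        up_set = all_names - down_set
        # keep the subtree below the node, remove everything else
        n_sites = site_count(scores.down[nid], scores.n_down[nid], t, refs)
        if n_sites > current_sites:
            out.append(CandidatePartition(
                node_id=nid, side=Side.keep_down,
                kept_names=down_set | ref_names, removed_names=up_set,
                n_removed=len(up_set), n_sites=n_sites,
                n_chars=int(scores.down[nid].sum()) + ref_chars,
            ))
        # keep the complement, remove the subtree below the node
        if scores.n_up[nid] >= 1:
            n_sites = site_count(scores.up[nid], scores.n_up[nid], t, refs)
            if n_sites > current_sites:
                out.append(CandidatePartition(
                    node_id=nid, side=Side.keep_up,
                    kept_names=up_set | ref_names, removed_names=down_set,
                    n_removed=len(down_set), n_sites=n_sites,
                    n_chars=int(scores.up[nid].sum()) + ref_chars,
                ))
    return out
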