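"""The greedy optimization loop.

Each iteration enumerates every improving tree bipartition side, ranks the
candidates (fewest sequences removed first, then most sites gained, then
most resolved characters kept, then a deterministic tie key), applies the
top feasible candidate, and updates the score arrays incrementally:

* keeping a *down* set restricts the tree to that subtree — all down arrays
  survive unchanged and only the up arrays are recomputed;
* keeping an *up* set prunes the complementary subtree — the down arrays on
  the path from the excision point to the root shrink by the removed
  subtree's counts, and the up arrays are recomputed.

The loop stops when no feasible improving candidate remains or a stopping
criterion fires (minimum final sequences, maximum sequences removed, or a
maximum cost in sequences removed per site gained, evaluated per step).
The diagnostic mode runs the same loop with no criteria to exhaustion and
records the full trade-off curve, including the mean per-column Shannon
entropy of the retained sub-alignment as a proxy for sequence diversity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import DomainError, IdentityError, StateError
from .guide_tree import GuideTree, TreeNode
from .msa_io import (
    Alignment,
    MissingSpec,
    PresenceMatrix,
    presence_matrix,
)
from .partition_scores import (
    CandidatePartition,
    NodeScores,
    ReferenceSet,
    Side,
    compute_down,
    compute_up,
    enumerate_candidates,
    site_count,
)

__all__ = [
    "StoppingCriteria",
    "TradeoffStep",
    "TradeoffCurve",
    "OptimizationResult",
    "rank_candidates",
    "apply_selection",
    "optimize",
    "tradeoff_curve",
    "mean_site_entropy",
]

Chooser = Callable[[list[CandidatePartition]], CandidatePartition | None]


@dataclass(frozen=True)
class StoppingCriteria:
    """When the greedy loop stops.

    At least one criterion must be set (or ``interactive`` on, in which case
    the user decides).  ``max_cost_per_site`` is a per-step bound: the loop
    halts before applying a step whose sequences-removed / sites-gained
    ratio exceeds it.
    """

    min_final_sequences: int | None = None
    max_sequences_removed: int | None = None
    max_cost_per_site: float | None = None
    min_relative_entropy: float | None = None
    interactive: bool = False

    def __post_init__(self) -> None:
        if (self.min_final_sequences is None
                and self.max_sequences_removed is None
                and self.max_cost_per_site is None
                and self.min_relative_entropy is None
                and not self.interactive):
            raise DomainError(
                "set at least one stopping criterion or enable interactive mode"
            )
        if self.min_final_sequences is not None and self.min_final_sequences < 1:
            raise DomainError("min_final_sequences must be >= 1")
        if self.max_sequences_removed is not None and self.max_sequences_removed < 0:
            raise DomainError("max_sequences_removed must be >= 0")
        if self.max_cost_per_site is not None and self.max_cost_per_site <= 0:
            raise DomainError("max_cost_per_site must be positive")
        if self.min_relative_entropy is not None and not 0.0 <= self.min_relative_entropy <= 1.0:
            raise DomainError("min_relative_entropy must be in [0, 1]")


@dataclass(frozen=True)
class TradeoffStep:
    """One record of the greedy path (step 0 is the initial state)."""

    step: int
    n_removed_cum: int
    frac_removed: float
    n_sites: int
    frac_site_gain: float
    removed_names: tuple[str, ...]
    mean_entropy: float


@dataclass(frozen=True)
class TradeoffCurve:
    steps: tuple[TradeoffStep, ...]

    @property
    def initial_sites(self) -> int:
        return self.steps[0].n_sites

    @property
    def final_sites(self) -> int:
        return self.steps[-1].n_sites


@dataclass(frozen=True)
class OptimizationResult:
    final_alignment: Alignment
    final_tree: GuideTree
    curve: TradeoffCurve
    site_mask: np.ndarray  # 0/1 per column: threshold satisfied in final set


def rank_candidates(cands: Sequence[CandidatePartition]) -> list[CandidatePartition]:
    """Order candidates by the four-key scheme.

    Keys: fewest sequences removed; most sites; most resolved characters in
    the kept matrix; then node id ascending with keep-down before keep-up so
    ties resolve deterministically.
    """
    return sorted(
        cands,
        key=lambda c: (c.n_removed, -c.n_sites, -c.n_chars, c.node_id,
                       0 if c.side is Side.keep_down else 1),
    )


def _recompute_path_down(scores: NodeScores, node: TreeNode,
                         removed_down: np.ndarray, removed_n: int,
                         removed_names: frozenset[str]) -> None:
    """Subtract a pruned subtree's counts from every ancestor's down state."""
    while node is not None:
        scores.down[node.id] = scores.down[node.id] - removed_down
        scores.n_down[node.id] -= removed_n
        scores.leaf_sets[node.id] = scores.leaf_sets[node.id] - removed_names
        node = node.parent  # type: ignore[assignment]


def apply_selection(tree: GuideTree, scores: NodeScores,
                    choice: CandidatePartition) -> tuple[GuideTree, NodeScores]:
    """Prune the tree to the chosen side and restore valid scores in place.

    Keep-down: the chosen subtree becomes the whole tree; down arrays are
    untouched and up arrays are recomputed.  Keep-up: the chosen subtree is
    excised, down arrays on the root path are decremented by its counts, a
    unary node created by the excision is collapsed, and up arrays are
    recomputed.  The result is identical to a from-scratch recomputation on
    the pruned tree.
    """
    node = tree.find(choice.node_id)
    if node is None or node.parent is None:
        raise StateError(
            f"candidate node {choice.node_id} is not a non-root node of the current tree"
        )
    if scores.leaf_sets.get(node.id) is None:
        raise StateError("scores are not current for this tree")

    if choice.side is Side.keep_down:
        old_ids = {n.id for n in tree.preorder()}
        node.parent.remove_child(node)
        node.length = None
        tree.root = node
        kept_ids = {n.id for n in tree.preorder()}
        scores.drop(old_ids - kept_ids)
    else:
        parent = node.parent
        removed_ids = {n.id for n in _subtree_preorder(node)}
        parent.remove_child(node)
        _recompute_path_down(scores, parent,
                             removed_down=scores.down[node.id],
                             removed_n=scores.n_down[node.id],
                             removed_names=scores.leaf_sets[node.id])
        scores.drop(removed_ids)
        if len(parent.children) == 1:
            # collapse the unary node left by the excision
            child = parent.children[0]
            if child.length is not None and parent.length is not None:
                child.length += parent.length
            grand = parent.parent
            if grand is None:
                child.parent = None
                tree.root = child
            else:
                grand.children[grand.children.index(parent)] = child
                child.parent = grand
            scores.drop([parent.id])
    compute_up(tree, scores)
    return tree, scores


def _subtree_preorder(node: TreeNode):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------

def _column_entropies(chars: np.ndarray, present: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) of resolved-character frequencies per column.

    Columns with fewer than two resolved characters contribute zero.
    """
    n_cols = chars.shape[1]
    out = np.zeros(n_cols)
    for i in range(n_cols):
        col = chars[present[:, i].astype(bool), i]
        if col.size < 2:
            continue
        _, counts = np.unique(col, return_counts=True)
        p = counts / col.size
        out[i] = float(-(p * np.log(p)).sum())
    return out


def mean_site_entropy(aln: Alignment, spec: MissingSpec | None = None) -> float:
    """Mean per-column Shannon entropy (natural log) over resolved characters.

    Gaps and unresolved placeholders are excluded from each column's
    frequency distribution; the mean runs over all columns, including
    invariant ones (which contribute zero).  This is the diversity proxy
    reported along the trade-off curve.
    """
    if spec is None:
        spec = MissingSpec.for_alphabet(aln.alphabet)
    pm = presence_matrix(aln, spec)
    chars = aln.char_matrix()
    if not spec.case_sensitive:
        chars = np.char.upper(chars)
    return float(_column_entropies(chars, pm.values).mean())


# ---------------------------------------------------------------------------
# The greedy loop
# ---------------------------------------------------------------------------

def _feasible(cand: CandidatePartition, stop: StoppingCriteria | None,
              removed_cum: int) -> bool:
    if stop is None:
        return True
    if (stop.min_final_sequences is not None
            and len(cand.kept_names) < stop.min_final_sequences):
        return False
    if (stop.max_sequences_removed is not None
            and removed_cum + cand.n_removed > stop.max_sequences_removed):
        return False
    return True


def _mean_entropy_of(names: frozenset[str], chars: np.ndarray,
                     present: np.ndarray, name_index: dict[str, int]) -> float:
    idx = sorted(name_index[n] for n in names)
    return float(_column_entropies(chars[idx], present[idx]).mean())


def _run_greedy(aln: Alignment, tree: GuideTree, spec: MissingSpec | None,
                refs: Sequence[str] | None, t: float,
                stop: StoppingCriteria | None,
                chooser: Chooser | None = None) -> OptimizationResult:
    if not 0.0 <= t <= 1.0:
        raise DomainError(f"threshold t must be in [0, 1], got {t}")
    if spec is None:
        spec = MissingSpec.for_alphabet(aln.alphabet)
    pm = presence_matrix(aln, spec)
    ref_names = tuple(refs) if refs else ()
    unknown = set(ref_names) - set(aln.names)
    if unknown:
        raise IdentityError(f"reference names not in alignment: {sorted(unknown)}")

    tree = tree.copy()
    tree_leaves = set(tree.leaf_names())
    # references may sit in the supplied guide tree; excise them before scoring
    in_tree_refs = set(ref_names) & tree_leaves
    if in_tree_refs:
        from .guide_tree import prune_leaves, root_if_needed

        prune_leaves(tree, in_tree_refs)
        tree = root_if_needed(tree)
        tree_leaves = set(tree.leaf_names())
    expected = set(aln.names) - set(ref_names)
    if tree_leaves != expected:
        raise IdentityError(
            "guide-tree leaves must match alignment names minus references; "
            f"missing={sorted(expected - tree_leaves)} extra={sorted(tree_leaves - expected)}"
        )
    refset = ReferenceSet.from_presence(pm, ref_names) if ref_names else None

    scores = compute_down(tree, pm)
    compute_up(tree, scores)
    current = site_count(scores.down[tree.root.id], scores.n_down[tree.root.id],
                         t, refset)

    chars = aln.char_matrix()
    if not spec.case_sensitive:
        chars = np.char.upper(chars)
    name_index = {n: i for i, n in enumerate(aln.names)}
    total0 = aln.n_seqs
    kept = frozenset(aln.names)

    steps: list[dict] = [dict(
        step=0, n_removed_cum=0, n_sites=current, removed_names=(),
        mean_entropy=_mean_entropy_of(kept, chars, pm.values, name_index),
    )]
    entropy0 = steps[0]["mean_entropy"]
    removed_cum = 0

    while True:
        cands = enumerate_candidates(tree, scores, refset, t, current)
        ranked = rank_candidates(cands)
        feasible = [c for c in ranked if _feasible(c, stop, removed_cum)]
        if not feasible:
            break
        if chooser is not None:
            choice = chooser(feasible)
            if choice is None:
                break
        else:
            choice = feasible[0]
        if (stop is not None and stop.max_cost_per_site is not None
                and choice.n_removed / (choice.n_sites - current)
                > stop.max_cost_per_site):
            break
        apply_selection(tree, scores, choice)
        removed_cum += choice.n_removed
        current = choice.n_sites
        kept = kept - choice.removed_names
        entropy = _mean_entropy_of(kept, chars, pm.values, name_index)
        steps.append(dict(
            step=len(steps), n_removed_cum=removed_cum, n_sites=current,
            removed_names=tuple(sorted(choice.removed_names)),
            mean_entropy=entropy,
        ))
        if (stop is not None and stop.min_relative_entropy is not None
                and entropy0 > 0
                and entropy / entropy0 < stop.min_relative_entropy):
            break

    final_sites = steps[-1]["n_sites"]
    curve = TradeoffCurve(steps=tuple(
        TradeoffStep(
            frac_removed=s["n_removed_cum"] / total0,
            frac_site_gain=((s["n_sites"] - steps[0]["n_sites"]) / final_sites
                            if final_sites > 0 else 0.0),
            **s,
        )
        for s in steps
    ))
    final_alignment = aln.subset(kept)
    counts = pm.values[[name_index[n] for n in final_alignment.names]].sum(axis=0)
    site_mask = (counts / len(kept) >= t).astype(np.int64)
    return OptimizationResult(
        final_alignment=final_alignment,
        final_tree=tree,
        curve=curve,
        site_mask=site_mask,
    )


def optimize(aln: Alignment, tree: GuideTree, spec: MissingSpec | None = None,
             refs: Sequence[str] | None = None, t: float = 1.0,
             stop: StoppingCriteria | None = None,
             chooser: Chooser | None = None) -> OptimizationResult:
    """Greedily remove bipartition sides to maximize usable columns.

    ``refs`` names protected reference sequences: they are excised from the
    guide tree, can never be removed, and their coverage is pooled into
    every partition score.  ``stop`` must set at least one criterion (use
    :func:`tradeoff_curve` for exhaustive diagnostics).  ``chooser``
    overrides the default take-top-ranked policy, e.g. for interactive use;
    it receives the feasible ranked candidates and returns one or ``None``
    to stop.
    """
    if stop is None:
        raise DomainError("optimize requires stopping criteria; "
                          "use tradeoff_curve for an exhaustive run")
    return _run_greedy(aln, tree, spec, refs, t, stop, chooser)


def tradeoff_curve(aln: Alignment, tree: GuideTree,
                   spec: MissingSpec | None = None,
                   refs: Sequence[str] | None = None,
                   t: float = 1.0) -> TradeoffCurve:
    """Diagnostic mode: run the greedy loop to exhaustion and record each step.

    The last step's site count is the maximum reachable by the greedy path;
    the fractional site gain of step k is (sites_k - sites_0) / sites_final,
    so the final step reports (final - initial) / final.
    """
    return _run_greedy(aln, tree, spec, refs, t, stop=None).curve


def curve_to_tsv(curve: TradeoffCurve, header_lines: Sequence[str] = ()) -> str:
    """Render a trade-off curve as TSV with optional '#' header lines."""
    lines = [f"# {h}" for h in header_lines]
    lines.append("step\tn_removed_cum\tfrac_removed\tn_sites\tfrac_site_gain"
                 "\tremoved_names\tmean_entropy")
    for s in curve.steps:
        lines.append(
            f"{s.step}\t{s.n_removed_cum}\t{s.frac_removed:.6g}\t{s.n_sites}"
            f"\t{s.frac_site_gain:.6g}\t{','.join(s.removed_names)}"
            f"\t{s.mean_entropy:.6g}"
        )
    return "\n".join(lines) + "\n"
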