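"""Shared fixtures and brute-force oracles for the test suite.

The oracles here deliberately avoid the dynamic-programming code paths:
site counts are recomputed by direct column scans over explicit leaf sets,
and tree bipartitions are enumerated by walking leaf sets per node.
"""

from __future__ import annotations

import numpy as np
import pytest

from msaprune.fixtures import generate_random
from msaprune.guide_tree import GuideTree, random_tree
from msaprune.msa_io import Alignment, PresenceMatrix, direct_site_count, presence_matrix
from msaprune.partition_scores import Side


def make_instance(seed: int, n_seq: int | None = None, n_cols: int | None = None,
                  missing_rate: float | None = None):
    """A reproducible random (alignment, tree, presence-matrix) triple."""
    rng = np.random.default_rng(seed)
    if n_seq is None:
        n_seq = int(rng.integers(4, 13))
    if n_cols is None:
        n_cols = int(rng.integers(10, 61))
    if missing_rate is None:
        missing_rate = float(rng.choice([0.1, 0.3, 0.6]))
    aln = generate_random(n_seq, n_cols, missing_rate, seed=seed)
    tree = random_tree(list(aln.names), seed=seed + 1)
    return aln, tree, presence_matrix(aln)


def node_leaf_sets(tree: GuideTree) -> dict[int, frozenset[str]]:
    """Leaf set below every node, computed by direct traversal (no scores)."""
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[node.id] = frozenset({node.leaf_name})
        else:
            acc: frozenset[str] = frozenset()
            for child in node.children:
                acc |= sets[child.id]
            sets[node.id] = acc
    return sets


def brute_partitions(tree: GuideTree, pm: PresenceMatrix, t: float,
                     ref_names: frozenset[str] = frozenset()):
    """Every up/down bipartition side of the tree, scored by direct scans.

    Yields (side, kept, removed, n_removed, n_sites, n_chars) with reference
    sequences pooled into the kept set, mirroring the candidate contract.
    """
    sets = node_leaf_sets(tree)
    all_names = sets[tree.root.id]
    out = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        down = sets[node.id]
        up = all_names - down
        for side, kept_tree, removed in (
            (Side.keep_down, down, up),
            (Side.keep_up, up, down),
        ):
            if not kept_tree:
                continue
            kept = kept_tree | ref_names
            idx = [pm.index(n) for n in kept]
            out.append((
                side, kept, removed, len(removed),
                direct_site_count(pm, kept, t),
                int(pm.values[idx].sum()),
            ))
    return out


def best_brute_choice(tree, pm, t, current_sites, ref_names=frozenset()):
    """The optimal improving bipartition side under the 4-key ranking."""
    improving = [p for p in brute_partitions(tree, pm, t, ref_names)
                 if p[4] > current_sites]
    if not improving:
        return None
    return min(improving, key=lambda p: (p[3], -p[4], -p[5]))


@pytest.fixture
def simple_alignment() -> Alignment:
    return Alignment(
        names=("a", "b", "c"),
        rows=("ACGT", "AC-T", "A--T"),
    )
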