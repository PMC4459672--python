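"""Deterministic synthetic alignments with planted missing-data structure.

Real alignments mix broadly covered positions with positions present in only
a few sequences.  The planted generator emulates the simplest such
structure: a core of (near-)fully resolved sequences plus one or more "bad"
clades that are resolved only on a short column interval.  Under full
coverage (t = 1.0) with a removal budget equal to the total clade size, the
unique optimal move is to remove exactly the planted clades — an optimum the
generator verifies by exhaustive subset enumeration whenever the instance is
small enough (<= 15 sequences), and guarantees by construction otherwise.

Generators are pure functions of their arguments including the seed, so
every test fixture is reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import DesignError, DomainError
from .guide_tree import GuideTree, TreeNode, random_tree
from .msa_io import Alignment, Alphabet, MissingSpec, direct_site_count, presence_matrix

__all__ = ["PlantedDesign", "generate_planted", "generate_random",
           "ENUMERATION_LIMIT"]

# 2^15 kept-subset evaluations with a column scan stay well under a second
ENUMERATION_LIMIT = 15

_NUC = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedDesign:
    """Blueprint for a planted instance.

    ``bad_clades`` is a list of ``(size, (start, stop))`` pairs: a clade of
    ``size`` sequences resolved only on columns ``start..stop-1`` (0-based,
    half-open).  ``point_missing_rate`` sprinkles independent missing
    characters over the core sequences.
    """

    n_core: int = 8
    bad_clades: tuple[tuple[int, tuple[int, int]], ...] = ((3, (90, 100)),)
    n_cols: int = 100
    point_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bad_clades",
                           tuple((int(s), (int(a), int(b)))
                                 for s, (a, b) in self.bad_clades))
        if self.n_core < 1 or self.n_cols < 1:
            raise DomainError("n_core and n_cols must be >= 1")
        if not 0.0 <= self.point_missing_rate <= 1.0:
            raise DomainError("point_missing_rate must be in [0, 1]")
        for size, (start, stop) in self.bad_clades:
            if size < 1:
                raise DomainError("clade size must be >= 1")
            if not (0 <= start < stop <= self.n_cols):
                raise DomainError(
                    f"clade interval ({start}, {stop}) outside [0, {self.n_cols})"
                )

    @property
    def n_total(self) -> int:
        return self.n_core + sum(s for s, _ in self.bad_clades)


def _random_rows(rng: np.random.Generator, n: int, n_cols: int) -> np.ndarray:
    return _NUC[rng.integers(0, 4, size=(n, n_cols))]


def generate_planted(design: PlantedDesign
                     ) -> tuple[Alignment, GuideTree, frozenset[str], int]:
    """Build a planted instance and its expected optimum.

    Returns ``(alignment, guide_tree, expected_removals, expected_sites)``
    where ``expected_removals`` is the set of sequences whose removal is the
    unique best move under t = 1.0 with a budget of the total clade size,
    and ``expected_sites`` the resulting usable-column count.  The guide
    tree hangs each clade as its own subtree next to the core subtree, so
    the optimum is reachable by the tree-guided greedy.  Raises
    :class:`DesignError` when enumeration shows the planted optimum is not
    unique (e.g. too much point missingness).
    """
    rng = np.random.default_rng(design.seed)
    names: list[str] = []
    rows: list[str] = []

    core_names = [f"core_{i + 1}" for i in range(design.n_core)]
    core = _random_rows(rng, design.n_core, design.n_cols)
    if design.point_missing_rate > 0:
        hit = rng.random((design.n_core, design.n_cols)) < design.point_missing_rate
        core[hit] = "-"
    names.extend(core_names)
    rows.extend("".join(r) for r in core)

    clade_names: list[list[str]] = []
    for c, (size, (start, stop)) in enumerate(design.bad_clades):
        cnames = [f"clade{c + 1}_{i + 1}" for i in range(size)]
        block = np.full((size, design.n_cols), "-", dtype="<U1")
        block[:, start:stop] = _random_rows(rng, size, stop - start)
        names.extend(cnames)
        rows.extend("".join(r) for r in block)
        clade_names.append(cnames)

    aln = Alignment(names=tuple(names), rows=tuple(rows),
                    alphabet=Alphabet.nucleotide)

    # guide tree: core subtree and each clade subtree as children of the root
    root = TreeNode()
    root.add_child(_subtree_over(core_names, design.seed + 1))
    for k, cnames in enumerate(clade_names):
        root.add_child(_subtree_over(cnames, design.seed + 2 + k))
    tree = GuideTree(root)

    planted = frozenset(n for cnames in clade_names for n in cnames)
    budget = len(planted)
    if design.n_total <= ENUMERATION_LIMIT:
        expected_removals, expected_sites = _enumerate_optimum(
            aln, budget, planted)
    else:
        expected_removals = planted
        expected_sites = direct_site_count(
            presence_matrix(aln), set(aln.names) - planted, 1.0)
    return aln, tree, expected_removals, expected_sites


def _subtree_over(names: list[str], seed: int) -> TreeNode:
    if len(names) == 1:
        return TreeNode(leaf_name=names[0])
    return random_tree(names, seed).root


def _enumerate_optimum(aln: Alignment, budget: int,
                       planted: frozenset[str]) -> tuple[frozenset[str], int]:
    """Exhaustive oracle: best removal set of size <= budget at t = 1.0.

    Verifies that the planted clades are the unique removal set achieving
    the maximal site count at minimal cost.
    """
    pm = presence_matrix(aln)
    all_names = list(aln.names)
    best_sites = -1
    best_cost = None
    best_sets: list[frozenset[str]] = []
    for k in range(0, budget + 1):
        for removed in combinations(all_names, k):
            kept = set(all_names) - set(removed)
            if not kept:
                continue
            sites = direct_site_count(pm, kept, 1.0)
            if sites > best_sites:
                best_sites, best_cost = sites, k
                best_sets = [frozenset(removed)]
            elif sites == best_sites:
                if k < best_cost:  # type: ignore[operator]
                    best_cost = k
                    best_sets = [frozenset(removed)]
                elif k == best_cost:
                    best_sets.append(frozenset(removed))
    if len(best_sets) != 1 or best_sets[0] != planted:
        raise DesignError(
            "planted clades are not the unique optimal removal set; "
            "reduce point_missing_rate or adjust the clade intervals"
        )
    return best_sets[0], best_sites


def generate_random(n_seq: int, n_cols: int, missing_rate: float,
                    seed: int) -> Alignment:
    """I.i.d. random alignment with independent per-character missingness."""
    if n_seq < 2 or n_cols < 1:
        raise DomainError("need n_seq >= 2 and n_cols >= 1")
    if not 0.0 <= missing_rate <= 1.0:
        raise DomainError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    chars = _random_rows(rng, n_seq, n_cols)
    hit = rng.random((n_seq, n_cols)) < missing_rate
    chars[hit] = "-"
    names = tuple(f"seq_{i + 1}" for i in range(n_seq))
    return Alignment(names=names, rows=tuple("".join(r) for r in chars),
                     alphabet=Alphabet.nucleotide)
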