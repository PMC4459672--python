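"""Ranking, incremental updates, the greedy loop, and entropy tracking."""

import math

import numpy as np
import pytest

from msaprune.errors import DomainError, IdentityError, StateError
from msaprune.fixtures import PlantedDesign, generate_planted, generate_random
from msaprune.guide_tree import random_tree
from msaprune.msa_io import Alignment, direct_site_count, presence_matrix
from msaprune.optimizer import (
    StoppingCriteria,
    apply_selection,
    mean_site_entropy,
    optimize,
    rank_candidates,
    tradeoff_curve,
)
from msaprune.partition_scores import (
    CandidatePartition,
    Side,
    compute_down,
    compute_up,
    enumerate_candidates,
    site_count,
)

from conftest import best_brute_choice, make_instance


def _cand(n_removed, n_sites, n_chars=0, node_id=0, side=Side.keep_down):
    return CandidatePartition(
        node_id=node_id, side=side, kept_names=frozenset({"x"}),
        removed_names=frozenset({"y"}), n_removed=n_removed,
        n_sites=n_sites, n_chars=n_chars,
    )


class TestRankCandidates:
    def test_four_key_order(self):
        cands = [_cand(2, 9), _cand(1, 3), _cand(1, 4)]
        ranked = rank_candidates(cands)
        assert [(c.n_removed, c.n_sites) for c in ranked] == [(1, 4), (1, 3), (2, 9)]

    def test_chars_break_site_ties(self):
        ranked = rank_candidates([_cand(1, 5, n_chars=10), _cand(1, 5, n_chars=20)])
        assert [c.n_chars for c in ranked] == [20, 10]

    def test_identical_keys_fall_back_to_node_and_side(self):
        a = _cand(1, 5, 9, node_id=4, side=Side.keep_up)
        b = _cand(1, 5, 9, node_id=4, side=Side.keep_down)
        c = _cand(1, 5, 9, node_id=2, side=Side.keep_up)
        assert rank_candidates([a, b, c]) == [c, b, a]

    def test_single_candidate(self):
        c = _cand(1, 2)
        assert rank_candidates([c]) == [c]


def _full_recompute(tree, pm):
    scores = compute_down(tree, pm)
    compute_up(tree, scores)
    return scores


def _assert_scores_equal(tree, scores, pm):
    fresh = _full_recompute(tree.copy(), pm)
    for node in tree.preorder():
        assert (scores.down[node.id] == fresh.down[node.id]).all()
        assert (scores.up[node.id] == fresh.up[node.id]).all()
        assert scores.n_down[node.id] == fresh.n_down[node.id]
        assert scores.n_up[node.id] == fresh.n_up[node.id]


class TestApplySelection:
    def _first_choice(self, tree, scores, pm, t, side=None):
        current = site_count(scores.down[tree.root.id],
                             scores.n_down[tree.root.id], t)
        cands = enumerate_candidates(tree, scores, None, t, current)
        if side is not None:
            cands = [c for c in cands if c.side is side]
        return rank_candidates(cands)[0] if cands else None

    # seeds chosen so both partition sides have an improving candidate
    @pytest.mark.parametrize("side", [Side.keep_down, Side.keep_up])
    @pytest.mark.parametrize("seed", [1, 4, 5, 6, 9, 10])
    def test_incremental_equals_full_recompute(self, seed, side):
        aln, tree, pm = make_instance(seed, n_seq=10)
        scores = _full_recompute(tree, pm)
        choice = self._first_choice(tree, scores, pm, 0.7, side)
        assert choice is not None
        apply_selection(tree, scores, choice)
        assert set(tree.leaf_names()) == set(choice.kept_names)
        _assert_scores_equal(tree, scores, pm)

    def test_keep_down_preserves_down_arrays(self):
        aln, tree, pm = make_instance(17, n_seq=10)
        scores = _full_recompute(tree, pm)
        choice = self._first_choice(tree, scores, pm, 0.7, Side.keep_down)
        assert choice is not None
        before = {nid: arr.copy() for nid, arr in scores.down.items()}
        apply_selection(tree, scores, choice)
        for node in tree.preorder():
            assert (scores.down[node.id] == before[node.id]).all()

    def test_keep_up_decrements_root_path(self):
        """Removing one leaf shrinks every ancestor's down by its row."""
        aln, tree, pm = make_instance(23, n_seq=8)
        scores = _full_recompute(tree, pm)
        current = site_count(scores.down[tree.root.id], 8, 0.7)
        cands = [c for c in enumerate_candidates(tree, scores, None, 0.7, current)
                 if c.side is Side.keep_up and c.n_removed == 1]
        assert cands, "instance chosen so a single-leaf removal improves it"
        choice = cands[0]
        (removed_name,) = choice.removed_names
        row = pm.row(removed_name)
        before = {nid: arr.copy() for nid, arr in scores.down.items()}
        ancestors = {nid for nid, names in scores.leaf_sets.items()
                     if removed_name in names and names != {removed_name}}
        apply_selection(tree, scores, choice)
        for node in tree.preorder():
            expected = before[node.id]
            if node.id in ancestors:
                expected = expected - row
            assert (scores.down[node.id] == expected).all()

    def test_stale_candidate_rejected(self):
        aln, tree, pm = make_instance(2, n_seq=8)
        scores = _full_recompute(tree, pm)
        ghost = _cand(1, 999, node_id=10_000)
        with pytest.raises(StateError):
            apply_selection(tree, scores, ghost)

    def test_twenty_sequential_steps_stay_exact(self):
        """Staircase instance: >= 20 single-sequence removals, each checked
        against a from-scratch recomputation."""
        design = PlantedDesign(
            n_core=5,
            bad_clades=tuple((1, (0, 10 * (k + 1))) for k in range(25)),
            n_cols=260,
            seed=4,
        )
        aln, tree, expected_removals, expected_sites = generate_planted(design)
        pm = presence_matrix(aln)
        scores = _full_recompute(tree, pm)
        steps = 0
        current = site_count(scores.down[tree.root.id], aln.n_seqs, 1.0)
        while True:
            cands = enumerate_candidates(tree, scores, None, 1.0, current)
            if not cands:
                break
            choice = rank_candidates(cands)[0]
            apply_selection(tree, scores, choice)
            current = choice.n_sites
            steps += 1
            _assert_scores_equal(tree, scores, pm)
        assert steps >= 20
        assert current == expected_sites


class TestOptimize:
    def test_fully_resolved_is_a_no_op(self):
        aln = generate_random(6, 30, 0.0, seed=0)
        tree = random_tree(list(aln.names), seed=1)
        res = optimize(aln, tree, t=1.0,
                       stop=StoppingCriteria(max_sequences_removed=5))
        assert res.final_alignment.names == aln.names
        assert len(res.curve.steps) == 1
        assert res.curve.final_sites == 30

    def test_planted_clade_recovered(self):
        aln, tree, expected_removals, expected_sites = generate_planted(
            PlantedDesign())
        res = optimize(aln, tree, t=1.0,
                       stop=StoppingCriteria(min_final_sequences=8))
        assert set(aln.names) - set(res.final_alignment.names) == expected_removals
        assert res.curve.final_sites == expected_sites == 100
        assert res.curve.initial_sites == 10

    def test_infeasible_budget_means_no_removals(self):
        aln, tree, _, _ = generate_planted(PlantedDesign())
        res = optimize(aln, tree, t=1.0,
                       stop=StoppingCriteria(min_final_sequences=11))
        assert res.final_alignment.names == aln.names
        assert res.curve.final_sites == 10

    def test_max_removed_budget_respected(self):
        aln, tree, _, _ = generate_planted(PlantedDesign())
        res = optimize(aln, tree, t=1.0,
                       stop=StoppingCriteria(max_sequences_removed=2))
        assert aln.n_seqs - res.final_alignment.n_seqs <= 2

    def test_cost_per_site_stops_before_expensive_step(self):
        # removing the 3-clade gains 90 sites at cost 3/90; a tighter cost
        # cap forbids the step entirely
        aln, tree, _, _ = generate_planted(PlantedDesign())
        cheap = optimize(aln, tree, t=1.0,
                         stop=StoppingCriteria(max_cost_per_site=1.0))
        assert cheap.curve.final_sites == 100
        expensive = optimize(aln, tree, t=1.0,
                             stop=StoppingCriteria(max_cost_per_site=0.01))
        assert expensive.curve.final_sites == 10

    def test_idempotent_on_own_output(self):
        aln, tree, _, _ = generate_planted(PlantedDesign(seed=3))
        stop = StoppingCriteria(min_final_sequences=8)
        first = optimize(aln, tree, t=1.0, stop=stop)
        again = optimize(first.final_alignment, first.final_tree, t=1.0, stop=stop)
        assert again.final_alignment.names == first.final_alignment.names
        assert len(again.curve.steps) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_step_matches_exhaustive_partition_search(self, seed):
        """Each chosen candidate is the best tree-compatible partition
        under the 4-key order, verified by brute enumeration."""
        aln, tree, pm = make_instance(seed, n_seq=9)
        t = [0.5, 0.7, 1.0][seed % 3]
        work = tree.copy()
        scores = _full_recompute(work, pm)
        current = direct_site_count(pm, aln.names, t)
        for _ in range(50):
            cands = enumerate_candidates(work, scores, None, t, current)
            if not cands:
                break
            choice = rank_candidates(cands)[0]
            best = best_brute_choice(work, pm, t, current)
            assert best is not None
            assert (choice.n_removed, choice.n_sites, choice.n_chars) == (
                best[3], best[4], best[5])
            apply_selection(work, scores, choice)
            current = choice.n_sites

    @pytest.mark.parametrize("seed", range(6))
    def test_references_survive_and_score_pooled(self, seed):
        aln = generate_random(9, 40, 0.4, seed=seed)
        refs = list(aln.names[:2])
        tree = random_tree(list(aln.names), seed=seed + 100)
        res = optimize(aln, tree, refs=refs, t=0.7,
                       stop=StoppingCriteria(max_sequences_removed=7))
        assert set(refs) <= set(res.final_alignment.names)
        # final site count equals a pooled direct count over the final set
        pm = presence_matrix(aln)
        assert res.curve.final_sites == direct_site_count(
            pm, res.final_alignment.names, 0.7)

    def test_tree_alignment_mismatch_rejected(self):
        aln = generate_random(5, 20, 0.3, seed=0)
        tree = random_tree(["x", "y", "z"], seed=0)
        with pytest.raises(IdentityError):
            optimize(aln, tree, t=1.0,
                     stop=StoppingCriteria(max_sequences_removed=1))

    def test_threshold_out_of_domain_rejected(self):
        aln = generate_random(5, 20, 0.3, seed=0)
        tree = random_tree(list(aln.names), seed=0)
        with pytest.raises(DomainError):
            optimize(aln, tree, t=1.5,
                     stop=StoppingCriteria(max_sequences_removed=1))

    def test_stopping_criteria_must_be_set(self):
        with pytest.raises(DomainError):
            StoppingCriteria()

    def test_optimize_requires_stop(self):
        aln = generate_random(5, 20, 0.3, seed=0)
        tree = random_tree(list(aln.names), seed=0)
        with pytest.raises(DomainError):
            optimize(aln, tree, t=1.0)


class TestTradeoffCurve:
    def test_fully_resolved_single_record(self):
        aln = generate_random(5, 15, 0.0, seed=2)
        tree = random_tree(list(aln.names), seed=3)
        curve = tradeoff_curve(aln, tree, t=1.0)
        assert len(curve.steps) == 1
        assert curve.steps[0].n_removed_cum == 0
        assert curve.steps[0].n_sites == 15

    def test_nested_bad_clades_step_per_clade(self):
        design = PlantedDesign(
            n_core=6, n_cols=120,
            bad_clades=((2, (0, 40)), (3, (0, 80))), seed=1)
        aln, tree, _, expected_sites = generate_planted(design)
        curve = tradeoff_curve(aln, tree, t=1.0)
        sites = [s.n_sites for s in curve.steps]
        assert sites == sorted(set(sites))  # strictly increasing
        assert curve.final_sites == expected_sites == 120
        assert len(curve.steps) == 3  # initial state + one step per clade

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_sites_and_final_gain_definition(self, seed):
        aln, tree, pm = make_instance(seed)
        curve = tradeoff_curve(aln, tree, t=0.7)
        sites = [s.n_sites for s in curve.steps]
        assert all(b > a for a, b in zip(sites, sites[1:]))
        removed = [s.n_removed_cum for s in curve.steps]
        assert all(b > a for a, b in zip(removed, removed[1:]))
        last = curve.steps[-1]
        assert last.frac_site_gain == pytest.approx(
            (curve.final_sites - curve.initial_sites) / curve.final_sites)


class TestMeanSiteEntropy:
    def test_constant_column_is_zero(self):
        aln = Alignment(names=("a", "b", "c", "d"), rows=("A", "A", "A", "A"))
        assert mean_site_entropy(aln) == 0.0

    def test_uniform_four_state_column(self):
        aln = Alignment(names=("a", "b", "c", "d"), rows=("A", "C", "G", "T"))
        assert mean_site_entropy(aln) == pytest.approx(math.log(4), abs=1e-12)

    def test_identical_sequences_zero(self):
        aln = Alignment(names=("a", "b"), rows=("ACGT", "ACGT"))
        assert mean_site_entropy(aln) == 0.0

    def test_missing_chars_excluded_from_distribution(self):
        # resolved characters in the column are A,A -> entropy 0 despite gaps
        aln = Alignment(names=("a", "b", "c", "d"), rows=("A", "A", "-", "N"))
        assert mean_site_entropy(aln) == 0.0

    def test_single_resolved_character_contributes_zero(self):
        aln = Alignment(names=("a", "b"), rows=("A-", "--"))
        assert mean_site_entropy(aln) == 0.0

    def test_case_folding(self):
        aln = Alignment(names=("a", "b"), rows=("a", "A"))
        assert mean_site_entropy(aln) == 0.0


def divergent_clade_instance():
    """Low-diversity core plus divergent clades that carry the missing data.

    Removing a divergent clade both gains sites and drops diversity, so the
    mean site entropy must fall (or stay flat) along the greedy curve.
    """
    rng = np.random.default_rng(7)
    n_cols = 120
    core = ["A" * n_cols for _ in range(6)]
    names = [f"core_{i}" for i in range(6)]
    rows = list(core)
    for c, (size, (start, stop)) in enumerate([(2, (80, 120)), (3, (100, 120))]):
        for i in range(size):
            chars = np.full(n_cols, "-", dtype="<U1")
            chars[start:stop] = np.array(list("ACGT"))[
                rng.integers(0, 4, stop - start)]
            rows.append("".join(chars))
            names.append(f"div{c}_{i}")
    aln = Alignment(names=tuple(names), rows=tuple(rows))
    from msaprune.guide_tree import GuideTree, TreeNode, random_tree as rt

    root = TreeNode()
    root.add_child(rt(names[:6], seed=0).root)
    root.add_child(rt(names[6:8], seed=1).root)
    root.add_child(rt(names[8:11], seed=2).root)
    return aln, GuideTree(root)


def test_entropy_non_increasing_on_divergent_clade_fixture():
    aln, tree = divergent_clade_instance()
    curve = tradeoff_curve(aln, tree, t=1.0)
    assert len(curve.steps) >= 2
    ent = [s.mean_entropy for s in curve.steps]
    assert all(b <= a + 1e-12 for a, b in zip(ent, ent[1:]))
    assert ent[-1] < ent[0]
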