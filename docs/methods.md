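# Methods

## Model and procedure

`msaprune` treats an alignment purely through its *presence structure*: a
0/1 matrix marking, for each sequence and column, whether the character is
resolved (not a gap and not an unresolved placeholder). Gap and unresolved
characters are scored identically; the distinction is kept only for
reporting. Ambiguity codes other than `N`/`X` (e.g. `R`, `Y`, `B`) count
as resolved by default because they still carry information; users can
extend the unresolved set. Classification is case-insensitive by default,
and terminal gaps are not distinguished from internal ones.

A column is usable at threshold `t` when its resolved fraction over the
kept sequences is **at least** `t` (closed comparison; ties count). `t` is
a minimum coverage: "at most 5 % missing" corresponds to `t = 0.95`. At
`t = 1.0` the counts reduce to the boolean no-missing-character rule; the
count-based arrays are the single implementation and the boolean rule is
just their limit case, so there is one code path to validate.

The optimizer is deliberately a *tree-guided greedy*, not a global subset
search: the guide tree restricts candidate removals to bipartition sides,
which makes each iteration linear in tree size after the two-traversal
initialization, and tends to group sequences with similar missingness so
that removals are phylogenetically coherent. The cost is that the global
optimum over all subsets is not guaranteed — only optimality per step
among tree-compatible moves, which the test suite verifies exhaustively on
small instances.

### Score arrays and their update

Down arrays are filled in one post-order traversal (leaf rows, then child
sums), up arrays in one pre-order traversal using
`up(N) = up(F) + down(F) − down(N)`, an equivalent but cheaper form of the
brother-sum rule that also covers multifurcations. The root's up array is
defined as all zeros with zero sequences, giving the recursion a uniform
base case. Conservation (`down + up = whole-column count` at every node)
is asserted in tests over hundreds of random instances.

After a selection, scores are updated incrementally rather than rebuilt:

* keeping a **down** set reroots the tree at the chosen node; every
  surviving down array is reused unchanged and the up arrays are
  recomputed in one pre-order pass;
* keeping an **up** set excises the complementary subtree; the down
  arrays on the path from the excision point to the root are decremented
  by the removed subtree's counts, the unary node left behind is collapsed
  (branch lengths summed when present), and the up arrays are recomputed.

The contract — incremental state identical to a from-scratch recomputation
on the pruned tree — is tested after every step of a 25-step run.

### Candidate ranking

Improving candidates (site count strictly above the current one) are
sorted by: fewest sequences removed; then most sites; then most resolved
characters in the kept data matrix (interpreting "total characters" as
resolved characters, since missing cells carry no data); then node id
ascending with keep-down before keep-up. The last key is arbitrary but
fixed, so the whole pipeline is deterministic — for a binary root the two
root children describe the same bipartition from both sides, both are
emitted, and the tie key picks one reproducibly.

### Reference sequences

References are removed from the guide tree before scoring and their
per-column resolved counts are pooled into every candidate's fraction.
Pooling means a candidate's site count always equals a direct count over
`kept ∪ references`, which is how the tests check it. References can never
be removed because they are simply not part of any bipartition.

### Stopping rules

* `min_final_sequences` — candidates that would overshoot the budget are
  *skipped*, not fatal: a cheaper improving candidate may still be taken,
  and the loop ends when no feasible improving candidate remains.
* `max_sequences_removed` — same skipping logic on the cumulative count.
* `max_cost_per_site` — evaluated per step as
  `n_removed / site_gain` of the candidate about to be applied; the loop
  stops *before* applying a step whose cost exceeds the cap. A cumulative
  variant was considered and rejected: the per-step form is the direct
  reading of "stop when additional sites become too expensive", and a
  cumulative cap would silently allow arbitrarily bad late steps after
  cheap early ones.
* `min_relative_entropy` — optional diversity floor: stop once the mean
  site entropy of the kept alignment falls below the given fraction of its
  initial value. Off by default; entropy is otherwise only reported.
* interactive — the CLI shows the top 10 ranked feasible candidates and
  reads a choice; an empty or zero answer stops.

`tradeoff_curve` runs the identical loop with no criteria to exhaustion.
The fractional site gain of step `k` is `(sites_k − sites_0) / sites_final`
(the final step therefore reports `(final − initial)/final`), and the
fraction removed is relative to the initial sequence count. Step 0 records
the untouched input so every curve has at least one row.

## Guide trees

The overlap distance between two rows is the alignment length minus the
number of columns where both are resolved; the full matrix is one integer
matrix product of the presence matrix with its transpose. Its diagonal is
each sequence's own missing-position count, consistent with applying the
definition to a pair of identical sequences.

Agglomeration is a hand-rolled O(n³) Lance–Williams loop rather than a
call into `scipy.cluster.hierarchy`, for one reason: deterministic
tie-breaking. Equal minimum distances merge the lexicographically smallest
index pair, so rebuilt trees are reproducible byte for byte; scipy leaves
tie order unspecified. On tie-free matrices the topologies are
cross-checked against scipy in the test suite. Median, centroid and Ward
updates operate on squared distances, following the standard formulation.
Only the merge order matters downstream (heights are discarded), and
branch lengths in user-supplied trees are carried through I/O but ignored
by the optimizer — the algorithms consume topology only. Clustering
refuses inputs above 10,000 sequences (configurable); at that scale an
external fast phylogeny program should produce the Newick guide tree.

Random guide trees are labelled-coalescent draws (repeated random joins),
which gives every rooted binary topology positive probability; they serve
as a sensitivity baseline, not as a recommended default.

Newick I/O goes through dendropy (underscores preserved); unrooted inputs
with trifurcating roots are kept as rooted polytomies, and a unary root
chain is collapsed so the root is always an inner node for ≥ 2 leaves.

## Entropy

Per column, the Shannon entropy (natural log) of the frequency
distribution of resolved characters only; columns with fewer than two
resolved characters contribute zero, and the mean runs over all columns.
Natural log is an arbitrary but fixed base (any base is a monotone
rescaling); the output headers state the convention. Entropy on real data
tends to fall along the greedy path when missingness concentrates in
divergent clades; that trend is asserted only on a constructed fixture
with that structure, because on arbitrary random data it need not hold.

## Synthetic data

The planted generator emulates the one feature of real families the
optimizer consumes: block-structured missingness. A core of fully (or
near-fully) resolved sequences plus clades resolved only on short column
intervals, with uniform random resolved characters — content is arbitrary
because the optimizer reads only the presence structure; entropy tests use
dedicated constructed columns instead. Under `t = 1.0` with a removal
budget equal to the total clade size, the unique optimum is removal of
exactly the planted clades; the generator *verifies* this by exhaustive
enumeration of all removal subsets whenever the instance has ≤ 15
sequences (2¹⁵ subset evaluations stay under a second) and raises a design
error otherwise, so fixture guarantees are checked, not assumed. What
passing these tests does **not** show: behaviour under realistic
substitution processes, indel length distributions, or alignment error —
the generator plants no such structure.

The random generator draws i.i.d. characters with independent per-cell
missingness — the worst case for the method (no structure to exploit), and
exactly what the DP-vs-oracle equivalence tests want, since agreement must
hold on any presence matrix whatsoever.

Problem sizes in the tests and the acceptance script (≤ 12–30 sequences,
≤ 300 columns, 200-instance batches) are chosen so exhaustive oracles are
feasible and the whole suite runs in seconds; the algorithms themselves
are linear per iteration in sequences × columns and handle real-family
sizes comfortably.

## Numerical choices and degenerate inputs

* Coverage comparisons use one shared expression (`counts / n ≥ t` in
  float64) in both the DP and the brute-force oracle, so threshold ties
  resolve identically everywhere.
* Fully resolved alignments produce zero candidates and a one-row curve;
  optimizing an already-optimized output is a no-op (idempotence is
  tested).
* A keep-down selection at a leaf leaves a single-leaf tree, which simply
  has no further candidates.
* Column indices are 0-based internally; user-facing reports are 1-based
  where positions are printed.

## Known limitations

* Greedy per-step optimality only; no guarantee against the unrestricted
  optimum over all subsets.
* No column removal: sites are gained solely by removing sequences; the
  site mask is reporting, not filtering.
* No alignment-quality assessment or redundancy filtering — those are
  complementary steps (quality maskers before or after; similarity
  reduction afterwards, since similarity measures are themselves distorted
  by missing data).
* Phylip output sanitizes names to the strict 10-character format (logged),
  so Phylip round-trips are not name-exact for long names; FASTA is.
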