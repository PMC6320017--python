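# Methods

## Model

A genetic map of one chromosome is encoded as a bucket order: a strict
partial order on the marker set that is negatively transitive, or
equivalently a totally ordered sequence of disjoint non-empty buckets.
Markers in one bucket are mutually incomparable — typically markers in
complete linkage disequilibrium, mapped to one position. Inter-bucket
genetic distances are deliberately discarded: only the order matters
for collinearity, and keeping distances would not change any result
below.

Two notions of agreement between maps π₁ (on D₁) and π₂ (on D₂) are
computed, both over the shared markers D = D₁ ∩ D₂:

- **common subsequence**: a sequence s of shared markers such that no
  later element strictly precedes an earlier one in either map
  (equivalently, bucket positions are non-decreasing along s in both);
- **common induced subsequence**: additionally, no two elements of s
  may be incomparable in *both* maps — the output never orders markers
  that neither input orders.

The longest of each kind (LCS, LCIS) is the deliverable. Because
incomparability in a bucket order is bucket membership (an equivalence
relation), both definitions reduce to consecutive-pair checks along s,
which the validators and the brute-force oracle exploit.

## Homogenization

`homogenize(π₁, π₂)` restricts π₁ to D and splits each of its buckets
into maximal groups whose members share a π₂ bucket; groups are ordered
by (position in π₁, position in π₂). Running it both ways yields two
orders with *identical* bucket sets, and the sets of common (induced)
subsequences of the pair are unchanged by the refinement. Two
implementations share this contract:

- `homogenize`: per-bucket comparison sort of (π₂-position, name)
  pairs, O(n log n) overall;
- `homogenize_linear`: one scan of π₂ in bucket order distributes the
  shared markers into per-π₁-bucket slots. The scan order leaves each
  slot sorted by π₂ position — a counting sort keyed by the π₂ bucket
  index — so splitting is one more linear pass. Expected O(n) with
  ordinary hashing.

The pair constructor asserts bucket-multiset equality of the two
refined orders before returning; a violation would indicate a bug, not
a data problem, hence an assertion rather than an exception.

## Canonical within-bucket order

Bucket elements are stored sorted lexicographically by marker name.
This fixes three things at once: bucket equality can be decided by
comparing first elements, the single LCS returned is reproducible
(matched buckets are emitted in lexicographic order), and the LCIS
representative of a matched bucket is its lexicographically smallest
marker. The underlying model leaves within-bucket order free; the
canonicalization is a reproducibility device only. Marker names are
case-sensitive opaque strings; bucket positions are 1-based everywhere,
including file output.

## Quadratic dynamic program (`lcs_dp`)

After homogenization the refined bucket sequences are permutations of
one another (ids 1..n_b assigned by position in refined order 1). The
classical LCS/heaviest-common-subsequence table over the two *bucket
sequences* is filled with match weight 1 (LCIS) or the bucket size
(LCS). Because every id occurs exactly once per sequence, matching at a
match cell is always optimal, which reduces each row to a running
maximum of its predecessor with one injected candidate — the fill is a
vectorized O(n_b²). Backtracking is deterministic: take the match,
otherwise decrement the column only when strictly better. `lcs_length`
keeps two rows (O(n_b) memory); `lcs` stores the full table.

Counting and enumeration use distinct-sequence semantics: an optimal
solution is a maximum-weight chain of matched buckets, and a matched
bucket of size m contributes a factor m! to the LCS count (its markers
may appear in any order) or m to the LCIS count (any marker may
represent it). Distinct chains are counted by the standard
inclusion–exclusion recurrence over the length table; uniqueness of ids
makes the subtraction exact. Counts use Python integers, so there is no
overflow. Enumeration walks the same table with memoized,
size-capped chain lists (deterministic backtrack order; the first
sequence equals the one `lcs` returns) and expands each chain into
lexicographically ordered permutations or representatives.

## Fast path (`lcs_fast`)

`preprocess` homogenizes, ids the buckets 1..n_b by position in refined
order 1, and tags each bucket of refined order 2 with its id via its
first element. The id sequence of refined order 2 is a permutation;
LCIS is its LIS and LCS its HIS with bucket sizes as weights. Index 0
of each info array is a sentinel (ids −1/−2) mirroring the array layout
of the preprocessing routine; sentinels never enter the solvers.

`his` (and `lis`, its unit-weight case) runs in O(n log n): a
right-to-left sweep with a prefix-maximum Fenwick tree over value ranks
computes tail[i], the best weight of an increasing run starting at i.
Reconstruction groups positions by tail weight. Within one group,
values strictly decrease as index increases (if i < j with v[i] < v[j],
positive weights force tail[i] > tail[j]), and any continuation of a
maximum-weight prefix must land in the group of the remaining weight
exactly. The greedy step — the smallest feasible value, found by binary
search inside the group — therefore yields the maximum-weight
subsequence with the lexicographically smallest value sequence. This is
the package-wide tie-break; the DP route may return a different (equally
optimal) solution, and only lengths are contracted to agree between the
two routes.

## Brute-force oracle

`oracle_lcs` performs depth-first extension of partial sequences using
only the definitional relational queries (bucket positions), never the
DP or the reduction. It returns the exact optimum and all optimal
sequences, and is guarded to shared domains of ≤ 10 markers because
the search is exponential by design. It anchors the randomized
equivalence tests for lengths, counts and enumerations.

## Synthetic map pairs

`simulate_pair` emulates a dense SNP map pair: n markers assigned
uniformly to n/10 buckets (empty buckets dropped), matching maps where
on the order of ten markers share each position through linkage
disequilibrium. The second map perturbs the first by exchanging the
positions of ⌊0.10 · n_b⌋ disjoint random bucket pairs (locally
mis-ordered segments) and relocating ⌊0.10 · n⌋ random markers to
uniformly chosen buckets (individually mis-placed markers). Swapped
pairs are arbitrary rather than adjacent — the generator's own choice
where several readings are defensible, documented here rather than
claimed canonical. All draws come from one `numpy` generator seeded by
the config, so a config reproduces a pair byte-for-byte.

What the generator does *not* emulate: maps with partially overlapping
marker sets (both simulated maps share the full domain), uneven bucket
sizes along the chromosome, position-dependent error rates, or
chromosome-level structural variants. Tests passing on simulated pairs
therefore demonstrate algorithmic correctness and scaling, not
robustness to every artefact of real mapping pipelines; the
classification and report layers are additionally exercised on the
hand-built worked example, which does have private markers.

## Problem sizes and numerical choices

The randomized equivalence suite uses 500 random pairs with shared
domains of ≤ 8 markers — the largest size at which exhaustive search
over all ordered arrangements stays fast — plus 200 all-singleton pairs
against a textbook total-order LCS. The scaling check runs the fast
path on a simulated 100,000-marker pair and cross-checks DP versus fast
lengths at 10,000 markers; these sizes exercise the O(n log n) path
well past the regime where the bucket count and the marker count
separate. Map positions are compared for exact equality when bucketing
a TSV map: published maps print tied markers at identical positions,
and any epsilon rule would silently rewrite the order structure.
Degenerate inputs are defined, not errors: empty tables give empty
orders, disjoint domains give empty results of length 0, and the empty
sequence counts as the single optimal solution when nothing is shared.

## Limitations

- Exactly two maps per comparison; multi-map LCS is NP-hard and out of
  scope, as is consensus-map construction.
- Inputs must be bucket orders; general DAG-shaped partial orders are
  rejected rather than coerced, since no faithful coercion exists.
- Enumeration materializes chain lists and is meant for solution sets
  up to the requested limit, not for astronomically degenerate inputs.
- The CLI reports and classifies; it does not draw dual-synteny plots.
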