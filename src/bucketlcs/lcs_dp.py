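"""Quadratic dynamic programming for bucket-order LCS and LCIS.

After homogenization the two orders carry identical buckets, so finding
a longest common subsequence of the maps reduces to a classical
(weighted) LCS over the two *bucket sequences*:

* LCIS — no two output markers may be incomparable in both maps, hence
  at most one marker per homogenized bucket: plain LCS of the bucket
  sequences, every match worth 1.
* LCS — a matched bucket contributes all of its markers (they may be
  arranged arbitrarily, since both maps leave them unordered): heaviest
  common subsequence with bucket size as the match weight.

Because homogenized buckets are pairwise distinct within each order,
the bucket sequences are permutations of one another; matching is then
always optimal at a match cell, which the matrix fill exploits.

The module also provides counting and enumeration of all optimal
solutions, and an independent brute-force oracle used by the test
suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import factorial

import numpy as np

from .homogenize import HomogenizedPair, homogenize_pair
from .orders import BucketOrder

__all__ = [
    "CommonSubsequence",
    "lcs",
    "lcs_length",
    "count_optimal",
    "enumerate_optimal",
    "oracle_lcs",
]

_ORACLE_MAX_DOMAIN = 10


@dataclass(frozen=True)
class CommonSubsequence:
    """A common (induced) subsequence of two bucket orders."""

    elements: tuple[str, ...]
    mode: str  # "lcs" or "lcis"

    @property
    def length(self) -> int:
        return len(self.elements)

    def is_valid_for(self, pi1: BucketOrder, pi2: BucketOrder) -> bool:
        """Check the defining conditions against the two input orders."""
        s = self.elements
        if not (pi1.is_subsequence(s) and pi2.is_subsequence(s)):
            return False
        if self.mode == "lcis":
            for a, b in itertools.pairwise(s):
                if pi1.incomparable(a, b) and pi2.incomparable(a, b):
                    return False
        return True


# ---------------------------------------------------------------------
# matrix machinery
# ---------------------------------------------------------------------

def _id_arrays(pair: HomogenizedPair) -> tuple[list[int], list[int]]:
    """Per-bucket integer ids.

    Bucket ids are the positions 1..n_b in the refined order 1; the
    refined order 2 carries the same buckets, so its id sequence is a
    permutation of 1..n_b.  Identity of two sorted buckets is decided by
    their first element.  Returns (ids2, sizes_by_id) where ids2[j-1]
    is the id of the j-th bucket of order 2 and sizes_by_id[i] the size
    of bucket id i (index 0 unused).
    """
    h1, h2 = pair.order1h, pair.order2h
    first_to_id = {b[0]: i for i, b in enumerate(h1.buckets, start=1)}
    ids2 = [first_to_id[b[0]] for b in h2.buckets]
    sizes = [0] + [len(b) for b in h1.buckets]
    return ids2, sizes


def _weights(sizes: list[int], induced: bool) -> list[int]:
    return [1] * len(sizes) if induced else sizes


def _fill_matrix(ids2: list[int], wts: list[int]) -> np.ndarray:
    """Full (n_b+1)x(n_b+1) prefix-optimum matrix.

    Row i is the running maximum of row i-1 with the single match
    candidate injected: since ids are a permutation, bucket i of order 1
    matches exactly one column, and matching there is always optimal.
    """
    nb = len(ids2)
    pos_of = [0] * (nb + 1)
    for j, idv in enumerate(ids2, start=1):
        pos_of[idv] = j
    L = np.zeros((nb + 1, nb + 1), dtype=np.int64)
    for i in range(1, nb + 1):
        prev = L[i - 1]
        row = L[i]
        np.copyto(row, prev)
        jm = pos_of[i]
        cand = prev[jm - 1] + wts[i]
        if cand > row[jm]:
            row[jm] = cand
        np.maximum.accumulate(row, out=row)
    return L


def _length_only(ids2: list[int], wts: list[int]) -> int:
    """Last matrix cell with O(n_b) memory (two rows)."""
    nb = len(ids2)
    pos_of = [0] * (nb + 1)
    for j, idv in enumerate(ids2, start=1):
        pos_of[idv] = j
    prev = np.zeros(nb + 1, dtype=np.int64)
    row = np.zeros(nb + 1, dtype=np.int64)
    for i in range(1, nb + 1):
        np.copyto(row, prev)
        jm = pos_of[i]
        cand = prev[jm - 1] + wts[i]
        if cand > row[jm]:
            row[jm] = cand
        np.maximum.accumulate(row, out=row)
        prev, row = row, prev
    return int(prev[nb])


def _backtrack(
    L: np.ndarray, ids2: list[int], pair: HomogenizedPair, induced: bool
) -> tuple[str, ...]:
    """One optimal solution, deterministic.

    At a match the diagonal is taken (always optimal here); otherwise
    the column is decremented only when strictly better, else the row —
    this fixed tie-break makes the returned sequence reproducible.
    """
    h1 = pair.order1h
    out: list[str] = []
    i = j = len(ids2)
    while i > 0 and j > 0:
        if ids2[j - 1] == i:
            bucket = h1.buckets[i - 1]
            if induced:
                out.append(bucket[0])
            else:
                out.extend(reversed(bucket))
            i -= 1
            j -= 1
        elif L[i, j - 1] > L[i - 1, j]:
            j -= 1
        else:
            i -= 1
    out.reverse()
    return tuple(out)


# ---------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------

def lcs(
    pi1: BucketOrder, pi2: BucketOrder, induced: bool = False
) -> CommonSubsequence:
    """One longest common (induced) subsequence of two bucket orders.

    For LCS, every marker of a matched bucket is emitted in canonical
    (lexicographic) order; for LCIS the lexicographically smallest
    marker represents the bucket.  Disjoint domains yield an empty
    result.
    """
    mode = "lcis" if induced else "lcs"
    pair = homogenize_pair(pi1, pi2)
    if not pair.common_domain:
        return CommonSubsequence((), mode)
    ids2, sizes = _id_arrays(pair)
    wts = _weights(sizes, induced)
    L = _fill_matrix(ids2, wts)
    return CommonSubsequence(_backtrack(L, ids2, pair, induced), mode)


def lcs_length(pi1: BucketOrder, pi2: BucketOrder, induced: bool = False) -> int:
    """Length of the LC(I)S without building a solution."""
    pair = homogenize_pair(pi1, pi2)
    if not pair.common_domain:
        return 0
    ids2, sizes = _id_arrays(pair)
    return _length_only(ids2, _weights(sizes, induced))


def _optimal_chain_table(
    L: np.ndarray, ids2: list[int], wts: list[int], factors: list[int]
) -> list[list[int]]:
    """Count optimal solutions for every prefix pair.

    N[i][j] sums, over the distinct optimal bucket chains of the prefix
    (i, j), the product of the per-bucket ``factors`` along the chain.
    Standard distinct-LCS counting with inclusion–exclusion; bucket ids
    are unique in each sequence, so a chain omitted from both reduced
    prefixes is counted exactly once by the subtraction.
    """
    nb = len(ids2)
    Ll = L.tolist()
    N = [[0] * (nb + 1) for _ in range(nb + 1)]
    for j in range(nb + 1):
        N[0][j] = 1
    for i in range(1, nb + 1):
        Ni, Np = N[i], N[i - 1]
        Li, Lp = Ll[i], Ll[i - 1]
        Ni[0] = 1
        for j in range(1, nb + 1):
            here = Li[j]
            total = 0
            if ids2[j - 1] == i and here == Lp[j - 1] + wts[i]:
                total += Np[j - 1] * factors[i]
            if Lp[j] == here:
                total += Np[j]
            if Li[j - 1] == here:
                total += Ni[j - 1]
            if Lp[j - 1] == here:
                # chains avoiding both row i and column j were counted twice
                total -= Np[j - 1]
            Ni[j] = total
    return N


def count_optimal(
    pi1: BucketOrder, pi2: BucketOrder, induced: bool = False
) -> int:
    """Number of distinct optimal sequences.

    Distinct-sequence semantics: a matched bucket of size m contributes
    a factor m! to an LCS count (its markers may be emitted in any
    order) and a factor m to an LCIS count (any one marker may represent
    it).  Python integers keep the arithmetic exact at any size.
    """
    pair = homogenize_pair(pi1, pi2)
    if not pair.common_domain:
        return 1  # the empty sequence is the sole optimum
    ids2, sizes = _id_arrays(pair)
    wts = _weights(sizes, induced)
    L = _fill_matrix(ids2, wts)
    factors = [1] * len(sizes)
    for i, m in enumerate(sizes[1:], start=1):
        factors[i] = m if induced else factorial(m)
    N = _optimal_chain_table(L, ids2, wts, factors)
    return N[len(ids2)][len(ids2)]


def _optimal_chains(
    L: np.ndarray, ids2: list[int], cap: int
) -> list[tuple[int, ...]]:
    """Up to ``cap`` distinct optimal bucket-id chains, in the order the
    deterministic backtracker would visit them (match, then row, then
    column decrements)."""
    nb = len(ids2)
    Ll = L.tolist()
    memo: dict[tuple[int, int], list[tuple[int, ...]]] = {}

    def rec(i: int, j: int) -> list[tuple[int, ...]]:
        if Ll[i][j] == 0:
            return [()]
        key = (i, j)
        got = memo.get(key)
        if got is not None:
            return got
        here = Ll[i][j]
        out: list[tuple[int, ...]] = []
        seen: set[tuple[int, ...]] = set()
        if j > 0 and i > 0 and ids2[j - 1] == i:
            for c in rec(i - 1, j - 1):
                cc = c + (i,)
                if cc not in seen:
                    seen.add(cc)
                    out.append(cc)
        if i > 0 and Ll[i - 1][j] == here:
            for c in rec(i - 1, j):
                if c not in seen:
                    seen.add(c)
                    out.append(c)
        if j > 0 and Ll[i][j - 1] == here:
            for c in rec(i, j - 1):
                if c not in seen:
                    seen.add(c)
                    out.append(c)
        del out[cap:]
        memo[key] = out
        return out

    return rec(nb, nb)


def enumerate_optimal(
    pi1: BucketOrder,
    pi2: BucketOrder,
    induced: bool = False,
    limit: int = 10,
) -> list[CommonSubsequence]:
    """Up to ``limit`` distinct optimal sequences, deterministic order.

    Bucket chains come in backtrack order (the first one expands to the
    same sequence :func:`lcs` returns); within a matched bucket, LCS
    permutations and LCIS representatives are emitted lexicographically.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    mode = "lcis" if induced else "lcs"
    pair = homogenize_pair(pi1, pi2)
    if not pair.common_domain:
        return [CommonSubsequence((), mode)]
    ids2, sizes = _id_arrays(pair)
    wts = _weights(sizes, induced)
    L = _fill_matrix(ids2, wts)
    h1 = pair.order1h
    results: list[CommonSubsequence] = []
    for chain in _optimal_chains(L, ids2, limit):
        if induced:
            options = [h1.buckets[i - 1] for i in chain]
            pools: list[list[tuple[str, ...]]] = [
                [(e,) for e in b] for b in options
            ]
        else:
            pools = [
                list(itertools.permutations(h1.buckets[i - 1]))
                for i in chain
            ]
        for combo in itertools.product(*pools):
            results.append(
                CommonSubsequence(
                    tuple(itertools.chain.from_iterable(combo)), mode
                )
            )
            if len(results) >= limit:
                return results
    return results


# ---------------------------------------------------------------------
# brute-force oracle (testing aid; shares no logic with the DP)
# ---------------------------------------------------------------------

def oracle_lcs(
    pi1: BucketOrder, pi2: BucketOrder, induced: bool = False
) -> tuple[int, list[tuple[str, ...]]]:
    """Exact optimum by exhaustive search over ordered arrangements.

    Depth-first extension of partial sequences: an element may follow
    the current last one when its bucket positions do not decrease in
    either order, and (induced mode) when the consecutive pair is not
    incomparable in both.  Because incomparability is bucket membership,
    consecutive checks imply the pairwise definition.  Guarded to small
    shared domains — the search is exponential by design.
    """
    common = sorted(pi1.domain & pi2.domain)
    if len(common) > _ORACLE_MAX_DOMAIN:
        raise ValueError(
            f"oracle limited to shared domains of <= {_ORACLE_MAX_DOMAIN}"
        )
    p1 = {e: pi1.bucket_position(e) for e in common}
    p2 = {e: pi2.bucket_position(e) for e in common}

    best = 0
    solutions: list[tuple[str, ...]] = [()]
    seq: list[str] = []
    used = [False] * len(common)

    def rec(last: str | None) -> None:
        nonlocal best, solutions
        k = len(seq)
        if k > best:
            best = k
            solutions = [tuple(seq)]
        elif k == best and k > 0:
            solutions.append(tuple(seq))
        for idx, e in enumerate(common):
            if used[idx]:
                continue
            if last is not None:
                if p1[e] < p1[last] or p2[e] < p2[last]:
                    continue
                if induced and p1[e] == p1[last] and p2[e] == p2[last]:
                    continue
            used[idx] = True
            seq.append(e)
            rec(e)
            seq.pop()
            used[idx] = False

    rec(None)
    return best, sorted(solutions)
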