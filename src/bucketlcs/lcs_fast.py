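"""O(n log n) LC(I)S via longest / heaviest increasing subsequences.

Homogenization leaves the two orders with identical buckets, so
numbering the buckets 1..n_b by their position in refined order 1 turns
refined order 2 into a permutation of 1..n_b.  A common (induced)
subsequence of the pair is then exactly an increasing run of that
identifier permutation:

* LCIS  — longest increasing subsequence (every bucket worth one
  representative marker);
* LCS   — heaviest increasing subsequence with bucket sizes as weights
  (every matched bucket contributes all of its markers).

Both are solved in O(n log n) with a Fenwick max tree, including full
reconstruction; among equally good solutions the lexicographically
smallest identifier sequence is returned, which pins the output down
deterministically.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass
from collections.abc import Sequence

from .homogenize import homogenize_pair
from .lcs_dp import CommonSubsequence
from .orders import BucketOrder

__all__ = [
    "BucketInfo",
    "IncreasingSubsequenceResult",
    "preprocess",
    "lis",
    "his",
    "lcs_fast",
]


@dataclass(frozen=True)
class BucketInfo:
    """One homogenized bucket with its integer identity.

    Equal ids mark equal buckets across the two info arrays; within one
    array ids are distinct.  The arrays carry a sentinel at index 0
    (ids -1 and -2, empty bucket) which never enters the LIS/HIS input.
    """

    bucket: tuple[str, ...]
    id: int
    nb_elt: int


@dataclass(frozen=True)
class IncreasingSubsequenceResult:
    """A strictly increasing subsequence and its score."""

    indices: tuple[int, ...]  # 0-based positions kept in the input
    values: tuple[int, ...]
    weight: int  # total weight for HIS; length for LIS

    @property
    def length(self) -> int:
        return len(self.indices)


def preprocess(
    pi1: BucketOrder, pi2: BucketOrder
) -> tuple[list[BucketInfo], list[BucketInfo]]:
    """Homogenize the pair and tag every bucket with an identifier.

    Ids are assigned 1..n_b by position in the refined order 1; each
    bucket of the refined order 2 recovers its id through its first
    element (all its elements share one refined-order-1 bucket).  Entry
    0 of each array is a sentinel excluded from downstream sequences.
    """
    pair = homogenize_pair(pi1, pi2)
    h1, h2 = pair.order1h, pair.order2h
    info1 = [BucketInfo((), -1, 0)]
    e_to_id: dict[str, int] = {}
    for i, b in enumerate(h1.buckets, start=1):
        info1.append(BucketInfo(b, i, len(b)))
        for e in b:
            e_to_id[e] = i
    info2 = [BucketInfo((), -2, 0)]
    for b in h2.buckets:
        info2.append(BucketInfo(b, e_to_id[b[0]], len(b)))
    return info1, info2


# ---------------------------------------------------------------------
# increasing-subsequence solvers
# ---------------------------------------------------------------------

class _MaxFenwick:
    """Prefix-maximum Fenwick tree over 1..n."""

    __slots__ = ("tree", "n")

    def __init__(self, n: int):
        self.n = n
        self.tree = [0] * (n + 1)

    def update(self, k: int, val: int) -> None:
        tree = self.tree
        while k <= self.n:
            if tree[k] < val:
                tree[k] = val
            k += k & -k

    def query(self, k: int) -> int:
        tree = self.tree
        best = 0
        while k > 0:
            if tree[k] > best:
                best = tree[k]
            k -= k & -k
        return best


def his(
    seq: Sequence[int], weights: Sequence[int]
) -> IncreasingSubsequenceResult:
    """Heaviest strictly increasing subsequence of distinct integers.

    A right-to-left Fenwick sweep computes, for every position, the best
    achievable weight of an increasing run starting there.  Positions
    are then grouped by that tail weight: within one group values
    strictly decrease with index (weights are positive), so the greedy
    reconstruction — smallest feasible value first — is a binary search
    per step.  The result is the maximum-weight subsequence whose value
    sequence is lexicographically smallest, in O(n log n) overall.
    """
    n = len(seq)
    if len(weights) != n:
        raise ValueError("seq and weights must have the same length")
    if n == 0:
        return IncreasingSubsequenceResult((), (), 0)
    if len(set(seq)) != n:
        raise ValueError("sequence values must be distinct")
    if min(weights) <= 0:
        raise ValueError("weights must be positive integers")

    order = sorted(range(n), key=seq.__getitem__)
    rank = [0] * n
    for r, i in enumerate(order):
        rank[i] = r  # 0-based; larger value <-> larger rank

    # tail[i]: best total weight of an increasing run starting at i
    fen = _MaxFenwick(n)
    tail = [0] * n
    for i in range(n - 1, -1, -1):
        key = n - 1 - rank[i]  # prefix of keys <-> values greater than seq[i]
        tail[i] = weights[i] + fen.query(key)
        fen.update(key + 1, tail[i])
    total = max(tail)

    groups: dict[int, list[int]] = defaultdict(list)
    for i, t in enumerate(tail):
        groups[t].append(i)  # ascending index, descending value

    kept: list[int] = []
    prev_i = -1
    prev_v: int | None = None
    remaining = total
    while remaining > 0:
        grp = groups[remaining]
        lo = bisect_right(grp, prev_i)
        cand = grp[lo:]
        if prev_v is None:
            hi = len(cand)
        else:
            # values descend along cand; keep the window still above prev_v
            lo2, hi = 0, len(cand)
            while lo2 < hi:
                mid = (lo2 + hi) // 2
                if seq[cand[mid]] > prev_v:
                    lo2 = mid + 1
                else:
                    hi = mid
        pick = cand[hi - 1]
        kept.append(pick)
        remaining -= weights[pick]
        prev_i, prev_v = pick, seq[pick]

    return IncreasingSubsequenceResult(
        tuple(kept), tuple(seq[i] for i in kept), total
    )


def lis(seq: Sequence[int]) -> IncreasingSubsequenceResult:
    """Longest strictly increasing subsequence of distinct integers.

    Unit-weight case of :func:`his`: same O(n log n) bound and the same
    lexicographically-smallest tie-break.
    """
    return his(seq, [1] * len(seq))


# ---------------------------------------------------------------------
# end-to-end fast path
# ---------------------------------------------------------------------

def lcs_fast(
    pi1: BucketOrder, pi2: BucketOrder, induced: bool = False
) -> CommonSubsequence:
    """LC(I)S of two bucket orders through the increasing-subsequence
    reduction; same length contract (and element emission rules) as the
    dynamic-programming route."""
    mode = "lcis" if induced else "lcs"
    _info1, info2 = preprocess(pi1, pi2)
    body = info2[1:]
    if not body:
        return CommonSubsequence((), mode)
    ids = [bi.id for bi in body]
    if induced:
        res = lis(ids)
    else:
        res = his(ids, [bi.nb_elt for bi in body])
    out: list[str] = []
    for j in res.indices:
        bucket = body[j].bucket
        if induced:
            out.append(bucket[0])
        else:
            out.extend(bucket)
    return CommonSubsequence(tuple(out), mode)
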