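"""Homogenization: refining two bucket orders onto identical buckets.

Two maps of the same chromosome rarely bucket their shared markers the
same way.  Homogenization restricts both orders to the shared marker set
D = D1 ∩ D2 and splits every bucket so that two markers share a bucket
in the refined orders exactly when they share a bucket in *both* inputs.
The refined orders then have the same buckets (possibly in different
sequence), and the common-subsequence structure of the pair is provably
unchanged, which is what lets the LCS machinery work at bucket
granularity.

The refined counterpart of order 1 sequences its buckets by (position
in order 1, position in order 2); symmetrically for order 2.
"""

from __future__ import annotations

from dataclasses import dataclass

from .orders import BucketOrder

__all__ = [
    "HomogenizedPair",
    "homogenize",
    "homogenize_linear",
    "homogenize_pair",
]


@dataclass(frozen=True)
class HomogenizedPair:
    """The two refined orders over their common marker domain.

    Both orders carry exactly the same buckets (as sets), so a bucket of
    one can be identified in the other by any single element.
    """

    order1h: BucketOrder
    order2h: BucketOrder
    common_domain: frozenset[str]


def homogenize(pi1: BucketOrder, pi2: BucketOrder) -> BucketOrder:
    """Refine ``pi1`` with respect to ``pi2``.

    Markers absent from ``pi2`` are dropped.  Each bucket of ``pi1`` is
    split between consecutive elements (taken in increasing position in
    ``pi2``) whenever those elements sit in different ``pi2`` buckets.
    Runs in O(n log n) from the per-bucket comparison sorts.
    """
    pos2 = pi2._pos
    out: list[list[str]] = []
    for bucket in pi1.buckets:
        tmp = sorted((pos2[e], e) for e in bucket if e in pos2)
        if not tmp:
            continue
        run_pos = tmp[0][0]
        run: list[str] = []
        for p, e in tmp:
            if p != run_pos:
                out.append(run)
                run = []
                run_pos = p
            run.append(e)
        out.append(run)
    return BucketOrder(out)


def homogenize_linear(pi1: BucketOrder, pi2: BucketOrder) -> BucketOrder:
    """Refine ``pi1`` with respect to ``pi2`` in linear time.

    Same contract as :func:`homogenize`.  Instead of sorting inside each
    bucket, the shared markers are distributed into per-bucket slots of
    ``pi1`` by a single scan of ``pi2`` in bucket order.  The scan order
    makes each slot already sorted by position in ``pi2`` (a counting
    sort with the ``pi2`` bucket index as the integer label), so buckets
    are split by one more linear pass.
    """
    pos1 = pi1._pos
    pos2 = pi2._pos
    slots: list[list[str]] = [[] for _ in range(pi1.n_buckets + 1)]
    for bucket in pi2.buckets:  # increasing pos2
        for e in bucket:
            i = pos1.get(e)
            if i is not None:
                slots[i].append(e)
    out: list[list[str]] = []
    for slot in slots[1:]:  # increasing pos1; within a slot pos2 increases
        if not slot:
            continue
        run_pos = pos2[slot[0]]
        run: list[str] = []
        for e in slot:
            p = pos2[e]
            if p != run_pos:
                out.append(run)
                run = []
                run_pos = p
            run.append(e)
        out.append(run)
    return BucketOrder(out)


def homogenize_pair(pi1: BucketOrder, pi2: BucketOrder) -> HomogenizedPair:
    """Refine both orders of a pair onto their common buckets."""
    h1 = homogenize_linear(pi1, pi2)
    h2 = homogenize_linear(pi2, pi1)
    # Refined orders must carry identical bucket sets.
    assert sorted(h1.buckets) == sorted(h2.buckets), (
        "homogenized orders disagree on their buckets"
    )
    return HomogenizedPair(h1, h2, h1.domain)
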