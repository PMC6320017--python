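"""Bucket-order model of a genetic map.

A genetic map orders markers along a chromosome, but markers in total
linkage disequilibrium (or mapped to the exact same position) cannot be
ordered relative to each other.  A *bucket order* captures this: the
marker set is partitioned into a totally ordered sequence of *buckets*,
and two markers are comparable exactly when they sit in different
buckets.  Formally a bucket order is a strict partial order that is also
negatively transitive, so incomparability is an equivalence relation and
its classes are the buckets.

This module provides the :class:`BucketOrder` container, its relational
queries, construction from positional map tables, and the plain-text
bucket-order format used throughout the package.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence

import pandas as pd

__all__ = [
    "BucketOrder",
    "InvalidOrderError",
    "UnknownMarkerError",
    "from_map_table",
]


class InvalidOrderError(ValueError):
    """Raised when an input does not describe a valid bucket order."""


class UnknownMarkerError(KeyError):
    """Raised when a relational query names a marker outside the domain."""


class BucketOrder:
    """An ordered sequence of disjoint, non-empty marker buckets.

    Buckets are normalized to list their elements in lexicographic order
    of marker name.  This canonical listing makes bucket equality a
    positional test (two equal buckets share their first element), which
    the LCS machinery relies on.  Bucket positions are 1-based.

    Parameters
    ----------
    buckets
        Iterable of iterables of marker names.  Buckets must be pairwise
        disjoint and non-empty; marker names are case-sensitive opaque
        strings.
    """

    __slots__ = ("_buckets", "_pos")

    def __init__(self, buckets: Iterable[Iterable[str]]):
        norm: list[tuple[str, ...]] = []
        pos: dict[str, int] = {}
        for i, bucket in enumerate(buckets, start=1):
            bt = tuple(sorted(bucket))
            if not bt:
                raise InvalidOrderError(f"bucket {i} is empty")
            for e in bt:
                if not isinstance(e, str):
                    raise InvalidOrderError(f"marker {e!r} is not a string")
                if e in pos:
                    raise InvalidOrderError(
                        f"marker {e!r} appears in more than one bucket"
                    )
                pos[e] = i
            norm.append(bt)
        self._buckets = tuple(norm)
        self._pos = pos

    # -- basic queries -------------------------------------------------

    @property
    def buckets(self) -> tuple[tuple[str, ...], ...]:
        """Buckets in order, each a lexicographically sorted tuple."""
        return self._buckets

    @property
    def domain(self) -> frozenset[str]:
        """The set of all markers placed on this order."""
        return frozenset(self._pos)

    @property
    def n_buckets(self) -> int:
        return len(self._buckets)

    @property
    def n_markers(self) -> int:
        return len(self._pos)

    def __len__(self) -> int:
        return len(self._pos)

    def __contains__(self, marker: str) -> bool:
        return marker in self._pos

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BucketOrder):
            return NotImplemented
        return self._buckets == other._buckets

    def __hash__(self) -> int:
        return hash(self._buckets)

    def __repr__(self) -> str:
        inner = ", ".join("{" + ",".join(b) + "}" for b in self._buckets)
        return f"BucketOrder({inner})"

    # -- relational queries --------------------------------------------

    def bucket_position(self, marker: str) -> int:
        """1-based index of the bucket containing ``marker``."""
        try:
            return self._pos[marker]
        except KeyError:
            raise UnknownMarkerError(marker) from None

    def bucket_of(self, marker: str) -> tuple[str, ...]:
        """The bucket (sorted tuple) containing ``marker``."""
        return self._buckets[self.bucket_position(marker) - 1]

    def precedes(self, x: str, y: str) -> bool:
        """True iff ``x`` strictly precedes ``y`` (earlier bucket)."""
        return self.bucket_position(x) < self.bucket_position(y)

    def incomparable(self, x: str, y: str) -> bool:
        """True iff ``x`` and ``y`` share a bucket (order unknown)."""
        return self.bucket_position(x) == self.bucket_position(y)

    def is_subsequence(self, s: Sequence[str]) -> bool:
        """Whether ``s`` is a subsequence of this bucket order.

        ``s`` qualifies when every element lies in the domain and no
        later element strictly precedes an earlier one, i.e. bucket
        positions along ``s`` are non-decreasing.  Total function:
        unknown markers simply make the result ``False``.
        """
        prev = 0
        for e in s:
            p = self._pos.get(e)
            if p is None or p < prev:
                return False
            prev = p
        return True

    # -- plain-text format ---------------------------------------------

    @classmethod
    def from_text(cls, text: str) -> "BucketOrder":
        """Parse the plain-text format: one bucket per line, markers
        comma-separated.  Blank lines and ``#`` comment lines are
        ignored."""
        buckets = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            buckets.append([m.strip() for m in line.split(",") if m.strip()])
        return cls(buckets)

    def to_text(self) -> str:
        """Serialize to the plain-text format (one bucket per line)."""
        return "\n".join(",".join(b) for b in self._buckets) + (
            "\n" if self._buckets else ""
        )


def from_map_table(
    table: pd.DataFrame, chromosome: str | None = None
) -> BucketOrder:
    """Build a bucket order from a positional genetic-map table.

    Markers sharing an identical position form one bucket; buckets are
    ordered by increasing position.  Inter-bucket distances are
    discarded — only the order matters for collinearity analysis.
    Positions compare by exact equality: tied markers on published maps
    are printed at identical positions, and epsilon merging would
    silently alter the order structure.

    Parameters
    ----------
    table
        DataFrame with columns ``marker`` and ``position`` and an
        optional ``chromosome`` column.
    chromosome
        If given, restrict to rows of that chromosome.  If omitted and
        the table spans several chromosomes, an error is raised because
        a single bucket order cannot meaningfully mix chromosomes.
    """
    if "marker" not in table.columns or "position" not in table.columns:
        raise InvalidOrderError(
            "map table needs 'marker' and 'position' columns"
        )
    sel = table
    if chromosome is not None:
        if "chromosome" not in table.columns:
            raise InvalidOrderError(
                "chromosome requested but table has no 'chromosome' column"
            )
        sel = table[table["chromosome"].astype(str) == str(chromosome)]
    elif "chromosome" in table.columns and sel["chromosome"].nunique() > 1:
        raise InvalidOrderError(
            "table spans several chromosomes; pass chromosome= to select one"
        )
    if sel.empty:
        return BucketOrder([])

    markers = sel["marker"].astype(str)
    dup = markers[markers.duplicated()]
    if not dup.empty:
        raise InvalidOrderError(
            f"duplicate marker {dup.iloc[0]!r} in map selection"
        )
    positions = pd.to_numeric(sel["position"], errors="raise")
    bad = positions[~positions.apply(math.isfinite)]
    if not bad.empty:
        raise InvalidOrderError(
            f"non-finite position for marker {markers.loc[bad.index[0]]!r}"
        )

    grouped = sorted(
        pd.Series(markers.values, index=positions.values)
        .groupby(level=0)
        .apply(list)
        .items()
    )
    return BucketOrder([names for _pos, names in grouped])
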