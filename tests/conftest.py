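"""Shared fixtures: the worked durum-style example pair and random
bucket-order generators (plain RNG and a hypothesis strategy)."""

from __future__ import annotations

import random

import pytest
from hypothesis import strategies as st

from bucketlcs import BucketOrder

# Worked example: two small maps of one chromosome that bucket their
# shared markers differently and each carry private markers.
PI1_BUCKETS = [
    {"k"}, {"a", "b"}, {"l", "c"}, {"d", "e", "f"}, {"i", "j"}, {"g", "h"},
]
PI2_BUCKETS = [
    {"g", "h"}, {"c", "d", "e", "f"}, {"m", "q"}, {"r", "a"}, {"b", "n"},
    {"o", "p", "l"},
]


@pytest.fixture
def pi1() -> BucketOrder:
    return BucketOrder(PI1_BUCKETS)


@pytest.fixture
def pi2() -> BucketOrder:
    return BucketOrder(PI2_BUCKETS)


def random_bucket_order(rng: random.Random, elements: list[str]) -> BucketOrder:
    """Random partition of ``elements`` into an ordered bucket sequence."""
    if not elements:
        return BucketOrder([])
    shuffled = elements[:]
    rng.shuffle(shuffled)
    n_buckets = rng.randint(1, len(shuffled))
    cuts = sorted(rng.sample(range(1, len(shuffled)), n_buckets - 1)) if n_buckets > 1 else []
    buckets, start = [], 0
    for c in cuts + [len(shuffled)]:
        buckets.append(shuffled[start:c])
        start = c
    return BucketOrder(buckets)


def random_pair(
    rng: random.Random, max_shared: int = 8
) -> tuple[BucketOrder, BucketOrder]:
    """Random order pair with bounded shared domain and private markers."""
    n_shared = rng.randint(0, max_shared)
    shared = [f"s{i}" for i in range(n_shared)]
    extra1 = [f"x{i}" for i in range(rng.randint(0, 3))]
    extra2 = [f"y{i}" for i in range(rng.randint(0, 3))]
    return (
        random_bucket_order(rng, shared + extra1),
        random_bucket_order(rng, shared + extra2),
    )


@st.composite
def bucket_orders(draw, alphabet: str = "abcdefghij", min_size: int = 0):
    """Hypothesis strategy for small bucket orders over a fixed alphabet."""
    markers = draw(
        st.lists(
            st.sampled_from(list(alphabet)),
            unique=True,
            min_size=min_size,
            max_size=len(alphabet),
        )
    )
    if not markers:
        return BucketOrder([])
    n = len(markers)
    cuts = draw(
        st.lists(st.integers(1, n - 1), unique=True, max_size=n - 1)
        if n > 1
        else st.just([])
    )
    bounds = [0] + sorted(cuts) + [n]
    return BucketOrder(
        [markers[a:b] for a, b in zip(bounds, bounds[1:]) if a < b]
    )
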