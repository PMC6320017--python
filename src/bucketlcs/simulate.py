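"""Synthetic map pairs for benchmarking and testing.

The generator emulates a pair of linkage maps of one chromosome built
from overlapping data: the first order assigns n markers uniformly at
random to n/10 buckets (matching the density of SNP maps where roughly
ten markers share each position through linkage disequilibrium); the
second order perturbs it by swapping 10% of the buckets and moving 10%
of the markers to random buckets.  Swaps model locally inverted or
mis-ordered map segments, moves model individually mis-placed markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orders import BucketOrder

__all__ = ["SimulationConfig", "simulate_pair"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated bucket-order pair.

    ``n_buckets`` defaults to ``n_markers // 10``; the perturbation
    fractions default to 0.10 each.  Everything is driven by ``seed``,
    so one config reproduces one exact pair.
    """

    n_markers: int
    n_buckets: int | None = None
    bucket_swap_fraction: float = 0.10
    marker_move_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        nb = self.resolved_buckets
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if not 1 <= nb <= self.n_markers:
            raise ValueError("need 1 <= n_buckets <= n_markers")
        for frac in (self.bucket_swap_fraction, self.marker_move_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def resolved_buckets(self) -> int:
        if self.n_buckets is not None:
            return self.n_buckets
        return max(1, self.n_markers // 10)


def simulate_pair(config: SimulationConfig) -> tuple[BucketOrder, BucketOrder]:
    """Draw one (map 1, map 2) pair.

    Map 1: markers ``m1..mn`` multinomially assigned to buckets (empty
    buckets dropped).  Map 2: ``floor(f_swap * n_buckets)`` disjoint
    random bucket pairs exchange positions, then ``floor(f_move * n)``
    random markers are relocated to uniformly chosen buckets; buckets
    emptied by the moves are dropped.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_markers
    nb = config.resolved_buckets
    markers = [f"m{i}" for i in range(1, n + 1)]

    assignment = rng.integers(0, nb, size=n)
    raw: list[list[str]] = [[] for _ in range(nb)]
    for m, b in zip(markers, assignment):
        raw[b].append(m)
    buckets1 = [b for b in raw if b]
    order1 = BucketOrder(buckets1)

    # bucket swaps
    buckets2 = [list(b) for b in buckets1]
    k1 = len(buckets2)
    n_swaps = int(config.bucket_swap_fraction * k1)
    n_swaps = min(n_swaps, k1 // 2)
    if n_swaps:
        chosen = rng.choice(k1, size=2 * n_swaps, replace=False)
        for a, b in zip(chosen[::2], chosen[1::2]):
            buckets2[a], buckets2[b] = buckets2[b], buckets2[a]

    # marker moves
    n_moves = int(config.marker_move_fraction * n)
    if n_moves:
        where = {m: i for i, b in enumerate(buckets2) for m in b}
        moved = rng.choice(n, size=n_moves, replace=False)
        targets = rng.integers(0, len(buckets2), size=n_moves)
        for mi, target in zip(moved, targets):
            m = markers[mi]
            buckets2[where[m]].remove(m)
            buckets2[int(target)].append(m)
            where[m] = int(target)

    order2 = BucketOrder([b for b in buckets2 if b])
    return order1, order2
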