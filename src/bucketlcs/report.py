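"""Marker classification and congruence summaries for dual-synteny plots.

Dual-synteny viewers draw the two maps side by side and link shared
markers; coloring the links by whether a marker belongs to the LC(I)S
makes collinear regions and breakpoints visible at a glance.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .homogenize import homogenize_pair
from .lcs_fast import lcs_fast
from .orders import BucketOrder

__all__ = ["MarkerClassification", "classify_markers", "congruence_report"]

LABELS = ("in_lcs", "conflicting", "only_map1", "only_map2")


@dataclass(frozen=True)
class MarkerClassification:
    """Per-marker synteny label over the union of the two map domains.

    ``in_lcs`` markers are exactly the elements of the computed LC(I)S;
    shared markers left out of it are ``conflicting``; the rest are
    private to one map.
    """

    labels: dict[str, str]
    mode: str

    def group(self, label: str) -> frozenset[str]:
        return frozenset(m for m, l in self.labels.items() if l == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.labels.items()), columns=["marker", "label"]
        )


def classify_markers(
    pi1: BucketOrder, pi2: BucketOrder, mode: str = "lcs"
) -> MarkerClassification:
    """Label every marker of either map by its collinearity status."""
    if mode not in ("lcs", "lcis"):
        raise ValueError("mode must be 'lcs' or 'lcis'")
    result = lcs_fast(pi1, pi2, induced=(mode == "lcis"))
    in_result = set(result.elements)
    d1, d2 = pi1.domain, pi2.domain
    labels: dict[str, str] = {}
    for m in d1 | d2:
        if m in in_result:
            labels[m] = "in_lcs"
        elif m in d1 and m in d2:
            labels[m] = "conflicting"
        elif m in d1:
            labels[m] = "only_map1"
        else:
            labels[m] = "only_map2"
    return MarkerClassification(labels, mode)


def congruence_report(pi1: BucketOrder, pi2: BucketOrder) -> dict:
    """Key figures of how well two maps agree.

    Lengths of the LCS and LCIS, domain sizes, shared-marker count, the
    homogenized bucket count, and the LCS/shared and LCIS/shared ratios
    (1.0 for perfectly collinear maps; ratios of an empty intersection
    are reported as 0.0).
    """
    pair = homogenize_pair(pi1, pi2)
    shared = len(pair.common_domain)
    lcs_len = lcs_fast(pi1, pi2, induced=False).length
    lcis_len = lcs_fast(pi1, pi2, induced=True).length
    return {
        "lcs_length": lcs_len,
        "lcis_length": lcis_len,
        "n_map1": len(pi1),
        "n_map2": len(pi2),
        "n_shared": shared,
        "n_homogenized_buckets": pair.order1h.n_buckets,
        "lcs_ratio": lcs_len / shared if shared else 0.0,
        "lcis_ratio": lcis_len / shared if shared else 0.0,
    }
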