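"""Bicluster match scores: average relevance and average module recovery.

Both are average best-match Jaccard scores between two bicluster
collections. Relevance asks how well each found bicluster represents some
true module; recovery asks how well each true module is found. By default
matching is on gene sets; a cell-set mode (gene x sample rectangles) is also
provided, and sample-set collections can be scored by placing the sample
sets in the gene-set role.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import Bicluster, BiclusterSet

__all__ = ["MatchScores", "jaccard", "module_match_score", "relevance_and_recovery"]

log = logging.getLogger(__name__)

MODES = ("genes", "genes_and_samples")


@dataclass(frozen=True)
class MatchScores:
    relevance: float
    recovery: float


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def _key(b: Bicluster, mode: str) -> frozenset:
    if mode == "genes":
        return b.gene_ids
    return b.cells


def module_match_score(m1: BiclusterSet, m2: BiclusterSet, mode: str = "genes") -> float:
    """Mean over biclusters of m1 of their best Jaccard match in m2."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if len(m1) == 0:
        raise ValueError("m1 must be nonempty")
    if len(m2) == 0:
        return 0.0
    keys2 = [_key(b, mode) for b in m2]
    total = 0.0
    for b1 in m1:
        k1 = _key(b1, mode)
        total += max(jaccard(k1, k2) for k2 in keys2)
    return total / len(m1)


def relevance_and_recovery(found: BiclusterSet, truth: BiclusterSet,
                           mode: str = "genes") -> MatchScores:
    """Relevance = match(found -> truth); recovery = match(truth -> found).

    An empty `found` set leaves relevance undefined by the formula; it is
    reported as 0 with a logged note.
    """
    if len(truth) == 0:
        raise ValueError("truth bicluster set must be nonempty")
    if len(found) == 0:
        log.warning("empty found bicluster set: reporting relevance = 0 by convention")
        return MatchScores(relevance=0.0, recovery=0.0)
    return MatchScores(
        relevance=module_match_score(found, truth, mode),
        recovery=module_match_score(truth, found, mode),
    )
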