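"""Post-processing of candidate communities.

Two-node candidates carry no topological variation and are dropped; the
remaining candidates are merged so that no pair overlaps beyond a threshold,
keeping at each merge whichever of the two originals or their union the
fitness function scores highest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .data_prep import _merge_passes, jaccard
from .graph_store import Community, WeightedGraph, induced_subgraph

__all__ = ["MergeParams", "remove_small", "merge_learned", "qi_overlap"]


def qi_overlap(a: frozenset, b: frozenset) -> float:
    """Neighborhood-affinity overlap |A∩B|^2 / (|A||B|).

    This algebraic form is this package's definition of the Qi-style overlap
    score; it penalises asymmetric containment more than the Jaccard
    coefficient does.
    """
    if not a or not b:
        raise ValueError("overlap of an empty set is undefined")
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


OVERLAP_MEASURES = {"jaccard": jaccard, "qi_overlap": qi_overlap}


@dataclass
class MergeParams:
    measure: str = "qi_overlap"
    threshold: float = 0.375
    max_passes: int = 100

    def __post_init__(self) -> None:
        if self.measure not in OVERLAP_MEASURES:
            raise ValueError(f"unknown overlap measure {self.measure!r}")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")


def remove_small(comms: list[Community]) -> list[Community]:
    """Drop all communities with fewer than 3 nodes."""
    out = [c for c in comms if c.n_c >= 3]
    if comms and not out:
        warnings.warn("all candidate communities had fewer than 3 nodes", stacklevel=2)
    return out


def merge_learned(
    comms: list[Community],
    model,
    graph: WeightedGraph,
    params: MergeParams,
) -> list[Community]:
    """Merge overlapping candidates, retaining the highest-fitness variant.

    Same iterative pass structure as the known-community merge, but when a
    pair exceeds the overlap threshold the two originals and their union are
    scored with the fitness function and only the single best-scoring of the
    three is kept (appended to the end of the working list).
    """
    overlap = OVERLAP_MEASURES[params.measure]

    def combine(a: Community, b: Community) -> Community:
        union = induced_subgraph(graph, a.nodes | b.nodes)
        union.score = model.score_community(union, graph)
        for c in (a, b):
            if c.score is None:
                c.score = model.score_community(c, graph)
        # ties favour the union, then the first-listed original
        best = max((union, a, b), key=lambda c: c.score)
        return best

    return _merge_passes(comms, overlap, params.threshold, combine, params.max_passes)
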