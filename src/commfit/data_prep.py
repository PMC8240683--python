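"""Known-community cleaning, merging, splitting, and negative sampling.

Positive examples are the known communities (e.g. gold-standard protein
complexes) induced on the network; negatives are random walks grown from
random seeds.  Train and test positives must be *edge independent*: no
network edge may be induced by both a train and a test community, otherwise
the held-out evaluation leaks topology seen in training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from .graph_store import Community, WeightedGraph, induced_subgraph, community_is_connected, neighbor_map

__all__ = [
    "NegativeSamplingParams",
    "SplitResult",
    "clean_communities",
    "merge_similar",
    "split_train_test",
    "sample_negatives",
    "filter_negatives",
    "read_communities",
    "write_communities",
]

log = logging.getLogger(__name__)

CommunitySet = list[Community]

MAX_MERGE_PASSES = 100


@dataclass
class SplitResult:
    train: CommunitySet
    test: CommunitySet
    ratio: float


@dataclass
class NegativeSamplingParams:
    scale_factor: float = 1.1
    size_min: int = 3
    size_max: int = 10
    distribution: str = "uniform"  # uniform | matched
    max_retries: int = 10

    def __post_init__(self) -> None:
        if self.scale_factor <= 1:
            raise ValueError("scale_factor must be > 1")
        if self.size_min < 3:
            raise ValueError("size_min must be >= 3")
        if self.distribution not in ("uniform", "matched"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


# --- io -------------------------------------------------------------------


def read_communities(path, graph: WeightedGraph | None = None, label: str = "positive") -> CommunitySet:
    """One community per line, whitespace-separated node ids.

    A trailing numeric token is treated as a score column when the line has
    at least 4 tokens and the token parses as a float while the rest of the
    community does not require it (writer emits scores for learned sets).
    """
    comms: CommunitySet = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            score = None
            if len(parts) >= 4:
                try:
                    score = float(parts[-1])
                    parts = parts[:-1]
                except ValueError:
                    score = None
            nodes = frozenset(parts)
            if graph is not None:
                nodes = frozenset(n for n in nodes if n in graph.g)
                if not nodes:
                    continue
                comm = induced_subgraph(graph, nodes, label=label)
            else:
                comm = Community(nodes=nodes, n_c=len(nodes), m_c=0, label=label)
            comm.score = score
            comms.append(comm)
    return comms


def write_communities(path, comms: CommunitySet, with_scores: bool = False) -> None:
    with open(path, "w") as fh:
        for c in comms:
            line = " ".join(sorted(c.nodes))
            if with_scores and c.score is not None:
                line += f"\t{c.score:.6f}"
            fh.write(line + "\n")


# --- cleaning and merging -------------------------------------------------


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a or not b:
        raise ValueError("jaccard of an empty set is undefined")
    return len(a & b) / len(a | b)


def clean_communities(raw: CommunitySet, graph: WeightedGraph) -> CommunitySet:
    """Drop tiny, disconnected and duplicate communities.

    Nodes absent from the network are removed first; then communities with
    fewer than 3 remaining nodes, internally disconnected communities, and
    exact duplicates are discarded.
    """
    if not raw:
        raise ValueError("no communities to clean")
    seen: set[tuple] = set()
    out: CommunitySet = []
    for c in raw:
        nodes = frozenset(n for n in c.nodes if n in graph.g)
        if len(nodes) < 3:
            continue
        comm = induced_subgraph(graph, nodes, label="positive")
        if not community_is_connected(graph, comm):
            continue
        if comm.key() in seen:
            continue
        seen.add(comm.key())
        out.append(comm)
    if not out:
        raise ValueError("all communities were removed during cleaning")
    return out


def _merge_passes(
    comms: CommunitySet,
    overlap: Callable[[frozenset, frozenset], float],
    threshold: float,
    combine: Callable[[Community, Community], Community],
    max_passes: int = MAX_MERGE_PASSES,
) -> CommunitySet:
    """Iterative in-order merging shared by the known-set and learned-set paths.

    Each pass walks the current list; the community under consideration is
    merged with its highest-overlap partner when that overlap reaches the
    threshold, both are removed, and the replacement is appended to the end
    of the list so it is available to later comparisons in the same pass.
    Repeats until a full pass performs no merge.
    """
    work = list(comms)
    for _ in range(max_passes):
        merged_any = False
        i = 0
        while i < len(work):
            ci = work[i]
            best_j, best_ov = -1, -1.0
            for j, cj in enumerate(work):
                if j == i:
                    continue
                ov = overlap(ci.nodes, cj.nodes)
                if ov > best_ov:
                    best_ov, best_j = ov, j
            if best_j >= 0 and best_ov >= threshold:
                cj = work[best_j]
                for k in sorted((i, best_j), reverse=True):
                    work.pop(k)
                work.append(combine(ci, cj))
                merged_any = True
                # do not advance: the element now at position i is unvisited
            else:
                i += 1
        if not merged_any:
            return work
    raise RuntimeError(
        f"merging did not converge within {max_passes} passes "
        f"(threshold={threshold}); the overlap structure may be degenerate"
    )


def merge_similar(comms: CommunitySet, graph: WeightedGraph, j: float = 0.6) -> CommunitySet:
    """Merge known communities until no pair has Jaccard >= ``j``."""

    def combine(a: Community, b: Community) -> Community:
        return induced_subgraph(graph, a.nodes | b.nodes, label="positive")

    return _merge_passes(comms, jaccard, j, combine)


# --- train/test split -----------------------------------------------------


def _edge_set(graph: WeightedGraph, c: Community) -> frozenset:
    sub = graph.g.subgraph(c.nodes)
    return frozenset(frozenset(e) for e in sub.edges())


def split_train_test(
    comms: CommunitySet,
    graph: WeightedGraph,
    train_frac: float = 0.7,
    max_iters: int = 20,
    rng_seed: int = 0,
) -> SplitResult:
    """Split into edge-independent train and test sets near ``train_frac``.

    Starts from a random split, then repeats rounds of two-direction
    transfers (a community sharing an induced edge with the other set is
    moved there immediately) followed by end-of-list rebalancing toward the
    target ratio, until a round leaves the sets independent.
    """
    if len(comms) < 2:
        raise ValueError("need at least 2 communities to split")
    rng = np.random.default_rng(rng_seed)
    edge_sets = {c.key(): _edge_set(graph, c) for c in comms}

    def overlaps(c: Community, others: Sequence[Community]) -> bool:
        es = edge_sets[c.key()]
        return any(es & edge_sets[o.key()] for o in others)

    order = list(rng.permutation(len(comms)))
    shuffled = [comms[i] for i in order]
    n_train = int(round(train_frac * len(comms)))
    n_train = min(max(n_train, 1), len(comms) - 1)
    train, test = shuffled[:n_train], shuffled[n_train:]

    for _ in range(max_iters):
        # train -> test transfers
        for c in list(train):
            if overlaps(c, test):
                train.remove(c)
                test.append(c)
        # test -> train transfers
        for c in list(test):
            if overlaps(c, train):
                test.remove(c)
                train.append(c)
        # end-of-list rebalancing toward the target ratio, never undoing
        # independence: a community is only moved if it shares no induced
        # edge with the destination set
        target = int(round(train_frac * len(comms)))
        while len(train) > target and test is not None:
            moved = False
            for c in reversed(train):
                if not overlaps(c, test):
                    train.remove(c)
                    test.append(c)
                    moved = True
                    break
            if not moved:
                break
        while len(train) < target:
            moved = False
            for c in reversed(test):
                if not overlaps(c, train):
                    test.remove(c)
                    train.append(c)
                    moved = True
                    break
            if not moved:
                break
        independent = not any(overlaps(c, test) for c in train)
        if independent and train and test:
            for c in train:
                c.label = "positive"
            for c in test:
                c.label = "positive"
            return SplitResult(train=train, test=test, ratio=len(train) / len(comms))
    raise RuntimeError(
        f"no edge-independent split found in {max_iters} iterations; "
        "we recommend restarting the algorithm with a different random split "
        "(rng_seed)"
    )


# --- negative sampling ----------------------------------------------------


def _random_walk(
    graph: WeightedGraph, target_size: int, rng: np.random.Generator, max_retries: int
) -> frozenset:
    """Grow a random seed to ``target_size`` nodes by uniform boundary picks.

    Retries with fresh seeds when the walk gets stuck in a component smaller
    than the target; returns the nearest achieved size after retries.
    """
    nodes = sorted(graph.nodes)
    best: frozenset = frozenset()
    for _ in range(max_retries + 1):
        seed = nodes[rng.integers(len(nodes))]
        members = {seed}
        steps = 0
        while len(members) < target_size and steps < 2 * target_size:
            nm = neighbor_map(graph, members)
            if len(nm) == 0:
                break
            keys = sorted(nm.entries)
            members.add(keys[rng.integers(len(keys))])
            steps += 1
        if len(members) == target_size:
            return frozenset(members)
        if len(members) > len(best):
            best = frozenset(members)
    return best


def sample_negatives(
    graph: WeightedGraph,
    positives: CommunitySet,
    params: NegativeSamplingParams,
    rng_seed: int = 0,
) -> CommunitySet:
    """Random-walk non-communities, ``scale_factor`` times the positive count.

    Target sizes span the positive size range; ``uniform`` splits the walks
    (almost) equally across sizes, ``matched`` follows the positive size
    histogram.  Every walk is connected by construction.
    """
    if graph.n == 0:
        raise ValueError("graph is empty")
    rng = np.random.default_rng(rng_seed)
    total = int(round(params.scale_factor * len(positives)))
    sizes = list(range(params.size_min, params.size_max + 1))
    max_component = max(len(c) for c in nx.connected_components(graph.g))
    if params.size_max > max_component:
        warnings.warn(
            f"graph's largest component ({max_component}) is smaller than "
            f"size_max ({params.size_max}); walks will be capped",
            stacklevel=2,
        )
    targets: list[int] = []
    if params.distribution == "uniform":
        base, extra = divmod(total, len(sizes))
        for idx, s in enumerate(sizes):
            targets.extend([s] * (base + (1 if idx < extra else 0)))
    else:  # matched
        pos_sizes = [c.n_c for c in positives]
        for s in sorted(set(pos_sizes)):
            k = int(round(params.scale_factor * pos_sizes.count(s)))
            targets.extend([s] * k)
    out: CommunitySet = []
    for t in targets:
        nodes = _random_walk(graph, t, rng, params.max_retries)
        if len(nodes) >= 2:
            out.append(induced_subgraph(graph, nodes, label="negative"))
    return out


def filter_negatives(
    negatives: CommunitySet, positives: CommunitySet, j_neg: float = 0.5
) -> CommunitySet:
    """Drop random walks that resemble a known community (Jaccard >= j_neg)."""
    kept = [
        c
        for c in negatives
        if all(jaccard(c.nodes, p.nodes) < j_neg for p in positives)
    ]
    removed = len(negatives) - len(kept)
    if removed:
        log.info("filter_negatives removed %d walks resembling communities", removed)
    return kept
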