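"""Candidate-community search: stochastic two-stage seed growth.

Each seed (a node or a maximal clique) is grown into a candidate community
by repeatedly adding a boundary neighbor.  Stage one picks the neighbor:
greedy on edge weight, or epsilon-greedy on the fitness function (with
probability epsilon a uniformly random neighbor, else the highest-scoring
candidate).  Stage two, optionally, accepts or rejects a score-worsening
addition: iterative simulated annealing (ISA) accepts with probability
exp(dS / T), T following the geometric schedule T = T0 * alpha^i, while the
pseudo-metropolis variant accepts with a constant probability k.

Growth guarantees (by construction): the subgraph stays connected, since
only boundary neighbors are added and the only removal is the last-added
node; every returned community scores at least 0.5.

Seeds are embarrassingly parallel; each seed draws from its own random
substream keyed by (global seed, seed node set), so results are identical
regardless of worker count or scheduling.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from math import exp
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from joblib import Parallel, delayed

from .graph_store import (
    Community,
    NeighborMap,
    WeightedGraph,
    extend_neighbor_map,
    induced_subgraph,
    neighbor_map,
)

__all__ = [
    "SearchParams",
    "SeedSpec",
    "select_seeds",
    "max_steps_smart",
    "grow_seed",
    "accept_step",
    "run_search",
]

HEURISTICS = (
    "greedy_edge_weight",
    "eps_greedy",
    "eps_greedy_isa",
    "eps_greedy_pseudo_metropolis",
)


@dataclass
class SearchParams:
    heuristic: str = "eps_greedy_isa"
    epsilon: float = 0.01
    T0: float = 1.75
    alpha: float = 0.005  # alpha > 1 heats rather than cools
    k_accept: float = 0.1
    t1: int = 500  # neighbor-sample cap before any evaluation
    t2: int = 50  # sorted-evaluation cap in the greedy branch
    max_steps: int = 20
    improvement_window: int = 10
    use_model_stop_for_greedy: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.heuristic not in HEURISTICS:
            raise ValueError(f"unknown heuristic {self.heuristic!r}")
        if not 0 <= self.epsilon <= 1:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.T0 <= 0 or self.alpha <= 0:
            raise ValueError("T0 and alpha must be positive")
        if not 0 < self.k_accept <= 1:
            raise ValueError("k_accept must lie in (0, 1]")
        if self.t2 > self.t1:
            raise ValueError("t2 must not exceed t1")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class SeedSpec:
    mode: str = "all_nodes"  # all_nodes | known_community_nodes | random_n | maximal_cliques
    n_random: int = 0


def select_seeds(
    graph: WeightedGraph,
    spec: SeedSpec,
    known: Sequence[Community] = (),
    rng_seed: int = 0,
) -> list[frozenset]:
    """Seed node-sets per the requested mode, in deterministic order."""
    if graph.n == 0:
        raise ValueError("graph is empty")
    if spec.mode == "all_nodes":
        return [frozenset([n]) for n in sorted(graph.nodes)]
    if spec.mode == "known_community_nodes":
        nodes = sorted({n for c in known for n in c.nodes if n in graph.g})
        return [frozenset([n]) for n in nodes]
    if spec.mode == "random_n":
        if spec.n_random > graph.n:
            raise ValueError("n_random exceeds the number of nodes")
        rng = np.random.default_rng(rng_seed)
        picks = rng.choice(sorted(graph.nodes), size=spec.n_random, replace=False)
        return [frozenset([n]) for n in picks]
    if spec.mode == "maximal_cliques":
        return [frozenset(c) for c in nx.find_cliques(graph.g)]
    raise ValueError(f"unknown seed mode {spec.mode!r}")


def max_steps_smart(known: Sequence[Community]) -> int:
    """Largest known-community size after discarding upper outliers.

    Outliers are sizes above the Tukey fence Q3 + 1.5 IQR (quartiles by
    linear interpolation); with no outliers this is simply the maximum size.
    """
    if not known:
        raise ValueError("known community set is empty")
    sizes = np.array(sorted(c.n_c for c in known), dtype=float)
    q1, q3 = np.percentile(sizes, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    within = sizes[sizes <= fence]
    return int(within.max()) if within.size else int(sizes.max())


def accept_step(
    S_old: float,
    S_new: float,
    iteration: int,
    params: SearchParams,
    rng: np.random.Generator,
) -> tuple[bool, float]:
    """Stage-two accept/reject rule; returns (accept, temperature used).

    Score improvements are always accepted.  For worsening additions, ISA
    accepts with probability exp((S_new - S_old) / T) at T = T0 * alpha^i,
    pseudo-metropolis with constant probability k.
    """
    T = params.T0 * params.alpha**iteration
    if T <= 0:
        raise ValueError("temperature must be positive")
    if S_new >= S_old:
        return True, T
    if params.heuristic == "eps_greedy_isa":
        p = exp((S_new - S_old) / T)
    elif params.heuristic == "eps_greedy_pseudo_metropolis":
        p = params.k_accept
    else:
        raise ValueError("accept_step applies only to the stage-two heuristics")
    return bool(rng.random() < p), T


def _sorted_keys(nm: NeighborMap) -> list[str]:
    return sorted(nm.entries)


def _best_weight_neighbor(nm: NeighborMap) -> str:
    """Highest max-edge-weight neighbor; ties go to the smallest node id."""
    return min(nm.entries, key=lambda v: (-nm.max_weight(v), v))


def _pick_epsilon_greedy(
    graph: WeightedGraph,
    members: set,
    nm: NeighborMap,
    model,
    params: SearchParams,
    rng: np.random.Generator,
) -> str:
    """Stage-one neighbor choice for the epsilon-greedy family."""
    keys = _sorted_keys(nm)
    if len(keys) > params.t1:
        idx = rng.choice(len(keys), size=params.t1, replace=False)
        keys = [keys[i] for i in sorted(idx)]
    if rng.random() < params.epsilon:
        return keys[int(rng.integers(len(keys)))]
    if len(keys) > params.t2:
        # keep the t2 candidates with the largest max edge weight
        keys = sorted(keys, key=lambda v: (-nm.max_weight(v), v))[: params.t2]
        keys.sort()
    scores = model.score_nodes(graph, [frozenset(members | {v}) for v in keys])
    best = int(np.argmax(scores))  # argmax returns the first (lexicographically
    # smallest, since keys are sorted) of any tied maxima
    return keys[best]


def grow_seed(
    graph: WeightedGraph,
    model,
    seed: Iterable[str],
    params: SearchParams,
    rng: np.random.Generator | None = None,
) -> Community | None:
    """Grow one seed into a candidate community, or None.

    The first step always adds the neighbor with the highest connecting edge
    weight; later steps follow the configured heuristic.  Termination: no
    boundary neighbors; fitness below 0.5 (the last-added node is removed
    first); no score improvement for ``improvement_window`` iterations
    (stage-two heuristics only); or ``max_steps`` additions.
    """
    if rng is None:
        rng = _seed_rng(params.rng_seed, frozenset(seed))
    members = {n for n in seed if n in graph.g}
    if len(members) < len(set(seed)):
        raise ValueError("seed contains nodes absent from the graph")
    if not members:
        return None
    nm = neighbor_map(graph, members)
    two_stage = params.heuristic in ("eps_greedy_isa", "eps_greedy_pseudo_metropolis")
    uses_model = params.heuristic != "greedy_edge_weight" or params.use_model_stop_for_greedy

    S_old = (
        model.score_community(induced_subgraph(graph, members), graph)
        if uses_model and len(members) >= 2
        else None
    )
    best_score = S_old if S_old is not None else -np.inf
    since_improvement = 0

    for step in range(params.max_steps):
        if len(nm) == 0:
            break
        if step == 0:
            cand = _best_weight_neighbor(nm)
        elif params.heuristic == "greedy_edge_weight":
            cand = _best_weight_neighbor(nm)
        else:
            cand = _pick_epsilon_greedy(graph, members, nm, model, params, rng)

        members.add(cand)
        extend_neighbor_map(graph, nm, members, cand)

        if uses_model:
            S_new = model.score_community(induced_subgraph(graph, members), graph)
        else:
            S_new = None

        if S_new is not None and S_new < 0.5:
            _remove_last(graph, members, nm, cand)
            break

        if two_stage and S_old is not None:
            accepted, _ = accept_step(S_old, S_new, step, params, rng)
            if not accepted:
                _remove_last(graph, members, nm, cand)
                since_improvement += 1
                if since_improvement >= params.improvement_window:
                    break
                continue

        if S_new is not None:
            if S_new > best_score:
                best_score = S_new
                since_improvement = 0
            else:
                since_improvement += 1
            S_old = S_new
        if two_stage and since_improvement >= params.improvement_window:
            break

    if len(members) < 2:
        return None
    comm = induced_subgraph(graph, members)
    comm.score = model.score_community(comm, graph)
    if comm.score < 0.5:
        return None
    return comm


def _remove_last(graph: WeightedGraph, members: set, nm: NeighborMap, node: str) -> None:
    members.remove(node)
    # rebuild the boundary entry for the removed node and prune stale edges
    for v, w in graph.neighbors(node):
        if v in nm:
            edges = [(m, ew) for m, ew in nm.connecting_edges(v) if m != node]
            if edges:
                nm.entries[v] = (max(ew for _, ew in edges), edges)
            else:
                nm.remove(v)
    still_adjacent = [(m, w) for m, w in graph.neighbors(node) if m in members]
    if still_adjacent:
        nm.entries[node] = (max(w for _, w in still_adjacent), still_adjacent)


def _seed_rng(global_seed: int, seed_nodes: frozenset) -> np.random.Generator:
    """Per-seed substream independent of worker layout."""
    digest = zlib.crc32("\x1f".join(sorted(seed_nodes)).encode())
    return np.random.default_rng(np.random.SeedSequence([global_seed, digest]))


def _grow_task(graph, model, seed, params):
    try:
        return seed, grow_seed(graph, model, seed, params), None
    except Exception as e:  # pragma: no cover - defensive
        return seed, None, str(e)


def _grow_batch(graph, model, seeds, params):
    return [_grow_task(graph, model, s, params) for s in seeds]


def run_search(
    graph: WeightedGraph,
    model,
    seeds: Sequence[frozenset],
    params: SearchParams,
    n_workers: int = 1,
) -> list[Community]:
    """Grow every seed independently and return the deduplicated candidates.

    Failures on individual seeds are reported and skipped; the output is
    ordered by sorted node tuple for reproducibility and is identical for
    any worker count under a fixed rng_seed.
    """
    if not seeds:
        raise ValueError("no seeds given")
    if n_workers == 1:
        results = [_grow_task(graph, model, s, params) for s in seeds]
    else:
        # chunk the seed list so the graph and model are serialized once per
        # worker batch rather than once per seed
        chunks = np.array_split(np.arange(len(seeds)), n_workers)
        batches = Parallel(n_jobs=n_workers, prefer="threads")(
            delayed(_grow_batch)(graph, model, [seeds[i] for i in idx], params)
            for idx in chunks
            if len(idx)
        )
        results = [r for batch in batches for r in batch]
    failures = [(s, err) for s, _, err in results if err]
    for s, err in failures:
        import logging

        logging.getLogger(__name__).warning("seed %s failed: %s", sorted(s), err)
    dedup: dict[tuple, Community] = {}
    for _, comm, err in results:
        if comm is not None and err is None:
            dedup.setdefault(comm.key(), comm)
    return [dedup[k] for k in sorted(dedup)]
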