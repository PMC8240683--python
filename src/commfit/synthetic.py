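"""Synthetic benchmarks with planted ground-truth communities.

Two generators: the toy graph of disconnected unit-weight cliques used as a
pipeline sanity check (every clique is a known community and should be
recovered exactly), and a planted-community network whose communities mix
the topologies observed in real protein complexes — cliques, stars, linear
chains, and hybrids between linear and clique — embedded in a background of
low-weight noise edges.

Intra-community edge weights are drawn from a normal(0.8, 0.1) truncated to
(0, 1], background weights from a truncated normal(0.1, 0.05): the two
regimes mimic the separation between confident and incidental interaction
scores in confidence-weighted interaction networks while leaving enough
overlap that the classes are learnable but not trivially so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_store import Community, WeightedGraph, graph_from_edges, induced_subgraph

__all__ = ["PlantedSpec", "make_clique_toy", "make_planted_graph", "make_labeled_fixture"]

TOPOLOGIES = ("clique", "star", "linear", "hybrid")


@dataclass
class PlantedSpec:
    n_communities: int = 50
    size_range: tuple[int, int] = (4, 9)
    topology_mix: dict = field(
        default_factory=lambda: {"clique": 0.4, "star": 0.2, "linear": 0.2, "hybrid": 0.2}
    )
    intra_weight_dist: tuple[float, float] = (0.8, 0.1)
    background_nodes: int = 100
    background_edge_prob: float = 0.03
    background_weight_dist: tuple[float, float] = (0.1, 0.05)
    overlap_prob: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.topology_mix.values()) - 1.0) > 1e-9:
            raise ValueError("topology proportions must sum to 1")
        if set(self.topology_mix) - set(TOPOLOGIES):
            raise ValueError(f"unknown topology in mix: {self.topology_mix}")
        if self.size_range[0] < 3:
            raise ValueError("minimum community size is 3")


def make_clique_toy(
    n_cliques: int = 10, sizes: list[int] | None = None
) -> tuple[WeightedGraph, list[Community]]:
    """Disjoint unit-weight cliques; each clique is one known community."""
    if sizes is None:
        sizes = [3 + (i % 6) for i in range(n_cliques)]
    if len(sizes) != n_cliques:
        raise ValueError("sizes must have one entry per clique")
    if min(sizes) < 3:
        raise ValueError("clique sizes must be >= 3")
    edges = []
    truth_nodes = []
    for ci, size in enumerate(sizes):
        names = [f"c{ci}n{j}" for j in range(size)]
        truth_nodes.append(names)
        for a in range(size):
            for b in range(a + 1, size):
                edges.append((names[a], names[b], 1.0))
    graph = graph_from_edges(edges)
    truth = [induced_subgraph(graph, ns, label="positive") for ns in truth_nodes]
    return graph, truth


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal draws rejected outside (0, 1]."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size - filled)
        ok = draw[(draw > 0) & (draw <= 1)]
        out[filled : filled + len(ok)] = ok
        filled += len(ok)
    return out


def _community_edges(kind: str, names: list[str], rng: np.random.Generator) -> list[tuple[str, str]]:
    size = len(names)
    if kind == "clique":
        return [(names[a], names[b]) for a in range(size) for b in range(a + 1, size)]
    if kind == "star":
        return [(names[0], names[j]) for j in range(1, size)]
    if kind == "linear":
        return [(names[j], names[j + 1]) for j in range(size - 1)]
    if kind == "hybrid":
        # a path plus each non-adjacent pair as a chord with probability 0.5
        edges = [(names[j], names[j + 1]) for j in range(size - 1)]
        for a in range(size):
            for b in range(a + 2, size):
                if rng.random() < 0.5:
                    edges.append((names[a], names[b]))
        return edges
    raise ValueError(kind)


def make_planted_graph(spec: PlantedSpec) -> tuple[WeightedGraph, list[Community]]:
    """Planted-community network with heterogeneous topologies and noise."""
    rng = np.random.default_rng(spec.rng_seed)
    kinds = list(spec.topology_mix)
    probs = np.array([spec.topology_mix[k] for k in kinds])
    edges: list[tuple[str, str, float]] = []
    truth_nodes: list[list[str]] = []
    node_counter = 0
    for ci in range(spec.n_communities):
        kind = kinds[rng.choice(len(kinds), p=probs)]
        size = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
        names = [f"p{node_counter + j}" for j in range(size)]
        node_counter += size
        # optional overlap: replace one member with a node of an earlier community
        if truth_nodes and rng.random() < spec.overlap_prob:
            donor = truth_nodes[int(rng.integers(len(truth_nodes)))]
            names[-1] = donor[int(rng.integers(len(donor)))]
            names = list(dict.fromkeys(names))
        pairs = _community_edges(kind, names, rng)
        ws = _truncated_normal(rng, *spec.intra_weight_dist, len(pairs))
        edges.extend((a, b, float(w)) for (a, b), w in zip(pairs, ws))
        truth_nodes.append(names)
    bg_names = [f"b{j}" for j in range(spec.background_nodes)]
    comm_names = sorted({n for ns in truth_nodes for n in ns})
    all_names = comm_names + bg_names
    # background noise: low-weight edges touching at least one background node
    cand = []
    for i, a in enumerate(bg_names):
        for b in all_names:
            if a != b and (b.startswith("b") and b > a or not b.startswith("b")):
                cand.append((a, b))
    mask = rng.random(len(cand)) < spec.background_edge_prob
    picked = [p for p, m in zip(cand, mask) if m]
    ws = _truncated_normal(rng, *spec.background_weight_dist, len(picked))
    edges.extend((a, b, float(w)) for (a, b), w in zip(picked, ws))
    graph = graph_from_edges(edges)
    truth = [induced_subgraph(graph, ns, label="positive") for ns in truth_nodes]
    return graph, truth


def make_labeled_fixture(spec: PlantedSpec):
    """Planted instance run through data preparation and feature extraction.

    Returns (graph, train matrix, test matrix, split) ready for fitness
    training tests.
    """
    from . import data_prep, features

    graph, truth = make_planted_graph(spec)
    cleaned = data_prep.clean_communities(truth, graph)
    merged = data_prep.merge_similar(cleaned, graph, j=0.6)
    split = data_prep.split_train_test(
        merged, graph, train_frac=0.7, max_iters=20, rng_seed=spec.rng_seed
    )
    sizes = [c.n_c for c in merged]
    params = data_prep.NegativeSamplingParams(
        scale_factor=1.1, size_min=max(3, min(sizes)), size_max=max(sizes)
    )
    negatives = data_prep.sample_negatives(graph, merged, params, rng_seed=spec.rng_seed)
    negatives = data_prep.filter_negatives(negatives, merged, j_neg=0.5)
    rng = np.random.default_rng(spec.rng_seed)
    order = rng.permutation(len(negatives))
    n_train = int(round(0.7 * len(negatives)))
    neg_train = [negatives[i] for i in order[:n_train]]
    neg_test = [negatives[i] for i in order[n_train:]]
    train = features.build_feature_matrix(split.train, neg_train, graph)
    test = features.build_feature_matrix(split.test, neg_test, graph)
    return graph, train, test, split
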