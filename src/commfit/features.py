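"""Topological community embeddings.

A community is represented by an 18-dimensional vector of topological
statistics of its induced subgraph, spanning size, edge-weight, degree,
cohesion and spectral axes.  The feature list below is this package's
canonical definition (versioned via FEATURE_VERSION); models store the list
they were trained with and refuse to score under a mismatched version.

Degenerate statistics (the variance of a single value, assortativity of a
regular graph) are defined as 0 rather than NaN so every connected community
of a finite graph embeds to a finite vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph_store import Community, WeightedGraph

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_VERSION",
    "FeatureMatrix",
    "density_fitness",
    "community_embedding",
    "build_feature_matrix",
]

FEATURE_VERSION = 1

FEATURE_NAMES: tuple[str, ...] = (
    "n_nodes",
    "n_edges",
    "density",
    "weight_total",
    "weight_mean",
    "weight_max",
    "weight_var",
    "weighted_degree_mean",
    "degree_max",
    "degree_median",
    "degree_var",
    "clustering_mean",
    "clustering_max",
    "clustering_var",
    "degree_assortativity",
    "spectral_radius",
    "diameter",
    "transitivity",
)

assert len(FEATURE_NAMES) == 18


@dataclass
class FeatureMatrix:
    """Labeled community embeddings: one row per community."""

    X: np.ndarray  # (n_comms, 18)
    y: np.ndarray  # 1 positive / 0 negative
    provenance: list[tuple[str, ...]]  # sorted node tuples, row-aligned

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.provenance):
            raise ValueError("rows, labels and provenance must align")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite entries")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        df["label"] = self.y
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def density_fitness(community: Community, graph: WeightedGraph) -> float:
    """Intra- minus inter-cluster density: the classical fitness baseline.

    delta_int = m_c / (n_c (n_c - 1) / 2); delta_ext = (# boundary edges) /
    (n_c (n - n_c)), defined as 0 when the community spans the whole graph.
    """
    n_c = community.n_c
    if n_c < 2:
        raise ValueError("density fitness needs at least 2 nodes")
    n = graph.n
    delta_int = community.m_c / (n_c * (n_c - 1) / 2)
    boundary = sum(
        1
        for u in community.nodes
        for v, _ in graph.neighbors(u)
        if v not in community.nodes
    )
    delta_ext = 0.0 if n_c == n else boundary / (n_c * (n - n_c))
    return delta_int - delta_ext


def _var(x: np.ndarray) -> float:
    return float(np.var(x)) if x.size > 1 else 0.0


def community_embedding(community: Community, graph: WeightedGraph) -> np.ndarray:
    """18-feature topological embedding of a connected community."""
    sub = graph.g.subgraph(community.nodes)
    if sub.number_of_nodes() < 2:
        raise ValueError("embedding needs at least 2 nodes")
    if not nx.is_connected(sub):
        raise ValueError("embedding undefined for a disconnected community")

    n_c = sub.number_of_nodes()
    m_c = sub.number_of_edges()
    weights = np.array([d["weight"] for _, _, d in sub.edges(data=True)], dtype=float)
    degrees = np.array([d for _, d in sub.degree()], dtype=float)
    wdegrees = np.array([d for _, d in sub.degree(weight="weight")], dtype=float)
    clustering = np.array(list(nx.clustering(sub).values()), dtype=float)

    density = m_c / (n_c * (n_c - 1) / 2)
    try:
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            assort = nx.degree_assortativity_coefficient(sub)
    except (ValueError, ZeroDivisionError):
        assort = np.nan
    if not np.isfinite(assort):
        assort = 0.0  # regular graphs have undefined assortativity

    adj = nx.to_numpy_array(sub, weight="weight")
    spectral_radius = float(np.max(np.linalg.eigvalsh(adj)))

    vec = np.array(
        [
            n_c,
            m_c,
            density,
            float(weights.sum()) if weights.size else 0.0,
            float(weights.mean()) if weights.size else 0.0,
            float(weights.max()) if weights.size else 0.0,
            _var(weights),
            float(wdegrees.mean()),
            float(degrees.max()),
            float(np.median(degrees)),
            _var(degrees),
            float(clustering.mean()),
            float(clustering.max()),
            _var(clustering),
            float(assort),
            spectral_radius,
            float(nx.diameter(sub)),
            float(nx.transitivity(sub)),
        ],
        dtype=float,
    )
    if not np.all(np.isfinite(vec)):
        bad = [FEATURE_NAMES[i] for i in np.where(~np.isfinite(vec))[0]]
        raise ValueError(f"non-finite features {bad} for community {community.key()}")
    return vec


def build_feature_matrix(
    pos: list[Community], neg: list[Community], graph: WeightedGraph
) -> FeatureMatrix:
    """Stack positive and negative embeddings into a labeled matrix."""
    if not pos or not neg:
        raise ValueError("both positive and negative sets must be nonempty")
    rows, labels, prov = [], [], []
    for label, comms in ((1, pos), (0, neg)):
        for c in comms:
            try:
                rows.append(community_embedding(c, graph))
            except ValueError as e:
                raise ValueError(f"embedding failed for {c.key()}: {e}") from e
            labels.append(label)
            prov.append(c.key())
    return FeatureMatrix(
        X=np.vstack(rows), y=np.array(labels, dtype=int), provenance=prov
    )
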