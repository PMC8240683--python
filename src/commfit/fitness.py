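"""Learning and applying the community fitness function.

The fitness function is the positive-class probability of a binary
classifier trained to separate known-community embeddings from random-walk
embeddings.  The default ``grid`` backend fits a small documented candidate
set of scaled pipelines and keeps the one with the best mean cross-validated
average precision; an ``automl`` backend delegates the search to TPOT when
it is installed, falling back to the grid otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    precision_recall_fscore_support,
)
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import FEATURE_NAMES, FEATURE_VERSION, FeatureMatrix, community_embedding, density_fitness
from .graph_store import Community, WeightedGraph

__all__ = ["FitnessModel", "DensityScorer", "train_model", "evaluate_model", "save_model", "load_model"]

MODEL_FORMAT_VERSION = 1


@dataclass
class FitnessModel:
    """A fitted scaler+classifier pipeline with its selection metadata."""

    pipeline: Pipeline
    cv_score: float
    candidate_name: str
    feature_names: tuple[str, ...] = FEATURE_NAMES
    feature_version: int = FEATURE_VERSION

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict_proba(X)[:, 1]

    def score_community(self, community: Community, graph: WeightedGraph) -> float:
        vec = community_embedding(community, graph)
        return float(self.score_matrix(vec[None, :])[0])

    def score_nodes(self, graph: WeightedGraph, node_sets: Sequence[frozenset]) -> np.ndarray:
        """Batch-score node sets (used per growth step by the search)."""
        from .graph_store import induced_subgraph

        X = np.vstack(
            [community_embedding(induced_subgraph(graph, ns), graph) for ns in node_sets]
        )
        return self.score_matrix(X)


class DensityScorer:
    """Density-difference fitness mapped to [0, 1], as a model-free baseline.

    The raw intra-minus-inter density lies in [-1, 1]; it is rescaled with
    (f + 1) / 2 so the search's 0.5 stopping threshold corresponds to a
    positive density difference.
    """

    cv_score = float("nan")
    candidate_name = "density_baseline"
    feature_names = FEATURE_NAMES
    feature_version = FEATURE_VERSION

    def score_community(self, community: Community, graph: WeightedGraph) -> float:
        return (density_fitness(community, graph) + 1.0) / 2.0

    def score_nodes(self, graph: WeightedGraph, node_sets: Sequence[frozenset]) -> np.ndarray:
        from .graph_store import induced_subgraph

        return np.array(
            [self.score_community(induced_subgraph(graph, ns), graph) for ns in node_sets]
        )


def _candidates(rng_seed: int) -> list[tuple[str, Pipeline]]:
    return [
        (
            "logistic_regression",
            Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "clf",
                        LogisticRegression(
                            max_iter=5000, class_weight="balanced", C=1.0
                        ),
                    ),
                ]
            ),
        ),
        (
            "random_forest",
            Pipeline(
                [
                    ("scale", StandardScaler()),
                    (
                        "clf",
                        RandomForestClassifier(
                            n_estimators=200,
                            class_weight="balanced",
                            random_state=rng_seed,
                        ),
                    ),
                ]
            ),
        ),
        (
            "gradient_boosting",
            Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("clf", GradientBoostingClassifier(random_state=rng_seed)),
                ]
            ),
        ),
    ]


def train_model(
    train: FeatureMatrix,
    cv_folds: int = 5,
    backend: str = "grid",
    rng_seed: int = 0,
) -> FitnessModel:
    """Select and fit the community fitness classifier.

    Model selection maximises mean cross-validated average precision (area
    under the PR curve) over the candidate pipelines; the winner is refit on
    the full training matrix.
    """
    classes = np.unique(train.y)
    if len(classes) < 2:
        raise ValueError("training matrix must contain both classes")
    if backend == "automl":
        try:
            import tpot  # noqa: F401
        except ImportError:
            warnings.warn(
                "automl backend requested but TPOT is not installed; "
                "falling back to the grid backend",
                stacklevel=2,
            )
            backend = "grid"
        else:
            return _train_automl(train, cv_folds, rng_seed)
    if backend != "grid":
        raise ValueError(f"unknown backend {backend!r}")

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)
    best_name, best_pipe, best_score = None, None, -np.inf
    for name, pipe in _candidates(rng_seed):
        scores = cross_val_score(
            pipe, train.X, train.y, cv=cv, scoring="average_precision"
        )
        mean = float(np.mean(scores))
        if mean > best_score:
            best_name, best_pipe, best_score = name, pipe, mean
    best_pipe.fit(train.X, train.y)
    return FitnessModel(
        pipeline=best_pipe, cv_score=best_score, candidate_name=best_name
    )


def _train_automl(train: FeatureMatrix, cv_folds: int, rng_seed: int) -> FitnessModel:
    """TPOT-backed model search behind the same contract as the grid."""
    from tpot import TPOTClassifier

    t = TPOTClassifier(
        generations=50,
        population_size=50,
        cv=cv_folds,
        scoring="average_precision",
        random_state=rng_seed,
        verbosity=0,
    )
    t.fit(train.X, train.y)
    pipe = t.fitted_pipeline_
    cv_score = float(max(v["internal_cv_score"] for v in t.evaluated_individuals_.values()))
    return FitnessModel(pipeline=pipe, cv_score=cv_score, candidate_name="automl")


def evaluate_model(
    model: FitnessModel, test: FeatureMatrix, train: FeatureMatrix | None = None
) -> dict:
    """Held-out report: AP, PR curve, point metrics and size-binned accuracy."""
    if len(np.unique(test.y)) < 2:
        raise ValueError("test matrix must contain both classes")
    report = _split_report(model, test)
    if train is not None:
        report["train"] = _split_report(model, train)
    return report


def _split_report(model: FitnessModel, data: FeatureMatrix) -> dict:
    scores = model.score_matrix(data.X)
    pred = (scores >= 0.5).astype(int)
    precision, recall, f1, _ = precision_recall_fscore_support(
        data.y, pred, average="binary", zero_division=0
    )
    curve_p, curve_r, curve_t = precision_recall_curve(data.y, scores)
    sizes = data.X[:, 0].astype(int)  # first feature is the node count
    size_accuracy = {}
    for s in sorted(set(sizes)):
        mask = sizes == s
        size_accuracy[int(s)] = {
            "n": int(mask.sum()),
            "accuracy": float((pred[mask] == data.y[mask]).mean()),
        }
    assert sum(v["n"] for v in size_accuracy.values()) == len(data.y)
    return {
        "average_precision": float(average_precision_score(data.y, scores)),
        "accuracy": float((pred == data.y).mean()),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "pr_curve": {
            "precision": curve_p.tolist(),
            "recall": curve_r.tolist(),
            "thresholds": curve_t.tolist(),
        },
        "size_accuracy": size_accuracy,
    }


def save_model(model: FitnessModel, path) -> None:
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_version": model.feature_version,
            "feature_names": list(model.feature_names),
            "cv_score": model.cv_score,
            "candidate_name": model.candidate_name,
            "pipeline": model.pipeline,
        },
        path,
    )


def load_model(path) -> FitnessModel:
    blob = joblib.load(path)
    if tuple(blob["feature_names"]) != FEATURE_NAMES or blob["feature_version"] != FEATURE_VERSION:
        raise ValueError(
            "model was trained with a different feature manifest than this "
            "features module provides"
        )
    return FitnessModel(
        pipeline=blob["pipeline"],
        cv_score=blob["cv_score"],
        candidate_name=blob["candidate_name"],
        feature_names=tuple(blob["feature_names"]),
        feature_version=blob["feature_version"],
    )
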