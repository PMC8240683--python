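"""End-to-end pipeline orchestration and parameter sweeps.

Stages: prepare (clean / merge / split / negatives) -> features -> train ->
search -> merge -> evaluate.  Every stage writes its artifact into the run
directory together with the fully-serialized configuration and a manifest,
so a run is reproducible from its directory alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import data_prep, features, fitness, metrics, postprocess, search
from .graph_store import WeightedGraph, load_edge_list, write_node_store
from .synthetic import PlantedSpec, make_clique_toy, make_planted_graph

__all__ = ["RunConfig", "run_pipeline", "parameter_sweep"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # inputs: either files, or a synthetic preset
    edges_path: str | None = None
    communities_path: str | None = None
    preset: str | None = None  # cliques | planted
    # graph
    weight_cutoff: float = 0.0
    # data prep
    merge_j: float = 0.6
    train_frac: float = 0.7
    split_max_iters: int = 20
    neg_scale: float = 1.1
    neg_distribution: str = "uniform"
    neg_filter_j: float = 0.5
    # fitness
    cv_folds: int = 5
    backend: str = "grid"
    scorer: str = "model"  # model | density
    # search
    seed_mode: str = "all_nodes"
    n_random_seeds: int = 0
    search: search.SearchParams = field(default_factory=search.SearchParams)
    max_steps: str | int = "auto"  # auto -> outlier-robust max known size
    n_workers: int = 1
    # postprocess
    merge: postprocess.MergeParams = field(default_factory=postprocess.MergeParams)
    # metrics
    qi_t: float = 0.5
    # global
    rng_seed: int = 0
    out_dir: str = "run"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sp = raw.pop("search", {})
        mp = raw.pop("merge", {})
        cfg = cls(**raw)
        cfg.search = search.SearchParams(**sp) if isinstance(sp, dict) else sp
        cfg.merge = postprocess.MergeParams(**mp) if isinstance(mp, dict) else mp
        return cfg


def _load_inputs(cfg: RunConfig) -> tuple[WeightedGraph, list]:
    if cfg.preset == "cliques":
        return make_clique_toy(10, [3, 4, 5, 6, 7, 8, 3, 4, 5, 6])
    if cfg.preset == "planted":
        return make_planted_graph(PlantedSpec(rng_seed=cfg.rng_seed))
    if cfg.preset is not None:
        raise ValueError(f"unknown preset {cfg.preset!r}")
    if not cfg.edges_path or not cfg.communities_path:
        raise ValueError("either a preset or edges/communities paths are required")
    graph = load_edge_list(cfg.edges_path, cfg.weight_cutoff)
    known = data_prep.read_communities(cfg.communities_path, graph)
    return graph, known


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    manifest: dict = {"stages": {}, "rng_seed": cfg.rng_seed,
                      "feature_version": features.FEATURE_VERSION}

    def stage(name):
        t0 = time.time()

        def done(**counts):
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 3), **counts}

        return done

    try:
        done = stage("prepare")
        graph, raw_known = _load_inputs(cfg)
        write_node_store(graph, out / "node_store")
        cleaned = data_prep.clean_communities(raw_known, graph)
        merged = data_prep.merge_similar(cleaned, graph, j=cfg.merge_j)
        split = data_prep.split_train_test(
            merged, graph, cfg.train_frac, cfg.split_max_iters, cfg.rng_seed
        )
        sizes = [c.n_c for c in merged]
        neg_params = data_prep.NegativeSamplingParams(
            scale_factor=cfg.neg_scale,
            size_min=max(3, min(sizes)),
            size_max=max(sizes),
            distribution=cfg.neg_distribution,
        )
        negatives = data_prep.sample_negatives(graph, merged, neg_params, cfg.rng_seed)
        negatives = data_prep.filter_negatives(negatives, merged, cfg.neg_filter_j)
        rng = np.random.default_rng(cfg.rng_seed)
        order = rng.permutation(len(negatives))
        n_tr = int(round(0.7 * len(negatives)))
        neg_train = [negatives[i] for i in order[:n_tr]]
        neg_test = [negatives[i] for i in order[n_tr:]]
        data_prep.write_communities(out / "train_pos.txt", split.train)
        data_prep.write_communities(out / "test_pos.txt", split.test)
        data_prep.write_communities(out / "train_neg.txt", neg_train)
        data_prep.write_communities(out / "test_neg.txt", neg_test)
        done(
            raw=len(raw_known), cleaned=len(cleaned), merged=len(merged),
            train_pos=len(split.train), test_pos=len(split.test),
            negatives=len(negatives),
        )

        # On graphs whose every connected subgraph is community-like (e.g.
        # the disconnected-clique toy), the random-walk negatives coincide
        # with sub-communities and may all be filtered away; the classifier
        # is then ill-posed and only the density scorer makes sense.
        degenerate = not neg_train or not neg_test
        if degenerate and cfg.scorer != "density":
            raise ValueError(
                "no usable negative communities after filtering; use the "
                "density scorer for graphs without non-community structure"
            )
        model = None
        if not degenerate:
            done = stage("features")
            train_m = features.build_feature_matrix(split.train, neg_train, graph)
            test_m = features.build_feature_matrix(split.test, neg_test, graph)
            train_m.write_tsv(out / "train_matrix.tsv")
            test_m.write_tsv(out / "test_matrix.tsv")
            done(train_rows=len(train_m.y), test_rows=len(test_m.y))

            done = stage("train")
            model = fitness.train_model(train_m, cfg.cv_folds, cfg.backend, cfg.rng_seed)
            fitness.save_model(model, out / "model.bin")
            model_report = fitness.evaluate_model(model, test_m, train_m)
            with open(out / "model_report.json", "w") as fh:
                json.dump(model_report, fh, indent=1)
            done(cv_score=round(model.cv_score, 4),
                 test_ap=round(model_report["average_precision"], 4))
        else:
            manifest["stages"]["features"] = {"skipped": "degenerate negatives"}
            manifest["stages"]["train"] = {"skipped": "degenerate negatives"}

        done = stage("search")
        scorer = fitness.DensityScorer() if cfg.scorer == "density" else model
        seeds = search.select_seeds(
            graph,
            search.SeedSpec(mode=cfg.seed_mode, n_random=cfg.n_random_seeds),
            known=merged,
            rng_seed=cfg.rng_seed,
        )
        sp = cfg.search
        if cfg.max_steps == "auto":
            sp.max_steps = search.max_steps_smart(merged)
        else:
            sp.max_steps = int(cfg.max_steps)
        sp.rng_seed = cfg.rng_seed
        candidates = search.run_search(graph, scorer, seeds, sp, cfg.n_workers)
        data_prep.write_communities(out / "candidates.txt", candidates, with_scores=True)
        done(seeds=len(seeds), candidates=len(candidates))

        done = stage("merge")
        kept = postprocess.remove_small(candidates)
        learned = postprocess.merge_learned(kept, scorer, graph, cfg.merge)
        data_prep.write_communities(out / "learned.txt", learned, with_scores=True)
        done(after_small=len(kept), learned=len(learned))

        done = stage("evaluate")
        known_all = split.train + split.test
        report = metrics.evaluate_sets(known_all, learned, qi_t=cfg.qi_t)
        with open(out / "eval_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        pr = metrics.cocomplex_edge_pr(known_all, learned)
        with open(out / "cocomplex_pr.tsv", "w") as fh:
            fh.write("threshold\tprecision\trecall\n")
            for t, p, r in pr:
                fh.write(f"{t:.6f}\t{p:.6f}\t{r:.6f}\n")
        done(**{k: round(v, 4) for k, v in report.to_dict().items()
                if k in ("qi_f1", "fmmf", "cmff", "unspa")})
    except Exception as e:
        failed = [s for s in ("prepare", "features", "train", "search", "merge", "evaluate")
                  if s not in manifest["stages"]]
        stage_name = failed[0] if failed else "unknown"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise RuntimeError(f"pipeline stage {stage_name!r} failed: {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def parameter_sweep(cfg: RunConfig, grid: list[dict]) -> "pd.DataFrame":
    """One pipeline run per grid point, sharing the prepared data and model.

    Each grid point may override search parameters (epsilon, T0, alpha,
    k_accept, heuristic) and the merge threshold/measure; rows are sorted by
    Qi F1 descending, failures recorded with NaN metrics.
    """
    import copy

    import pandas as pd

    if not grid:
        raise ValueError("empty sweep grid")
    rows = []
    base = Path(cfg.out_dir)
    for i, point in enumerate(grid):
        sub = copy.deepcopy(cfg)
        sub.out_dir = str(base / f"sweep_{i}")
        for key, val in point.items():
            if hasattr(sub.search, key):
                setattr(sub.search, key, val)
            elif hasattr(sub.merge, key):
                setattr(sub.merge, key, val)
            elif hasattr(sub, key):
                setattr(sub, key, val)
            else:
                raise ValueError(f"unknown sweep parameter {key!r}")
        row = {f"param_{k}": v for k, v in point.items()}
        try:
            run_dir = run_pipeline(sub)
            with open(run_dir / "eval_report.json") as fh:
                row.update(json.load(fh))
        except Exception as e:  # record and continue
            log.warning("sweep point %d failed: %s", i, e)
            row["error"] = str(e)
        rows.append(row)
    df = pd.DataFrame(rows)
    if "qi_f1" in df:
        df = df.sort_values("qi_f1", ascending=False).reset_index(drop=True)
    df.to_csv(base / "sweep.tsv", sep="\t", index=False)
    return df
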