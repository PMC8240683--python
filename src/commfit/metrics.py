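"""Evaluation of a learned community set against a known set.

Node-set based measures only; every measure is bounded in [0, 1].

Legacy measures: the Qi-style thresholded precision/recall/F1, the maximal
matching ratio (MMR), the clustering-wise sensitivity / positive predictive
value / geometric-mean accuracy (Sn, PPV, SPA), and a co-complex edge PR
curve.  Newly constructed measures: FMMF (maximum-weight one-to-one
bipartite matching of F-similarities, turned into precision and recall by
normalising the matching weight by |L| and |K| respectively), CMFF (average
of per-community best F-similarities), and UnSPA (an Sn/PPV variant giving
every community equal weight, removing the size bias of Sn and the
spurious-node blindness of PPV).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from math import sqrt
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .graph_store import Community

__all__ = [
    "EvalReport",
    "jaccard",
    "neighborhood_affinity",
    "f_similarity",
    "qi_prf",
    "sensitive_prf",
    "cmff",
    "fmmf",
    "mmr",
    "spa_and_unspa",
    "cocomplex_edge_pr",
    "evaluate_sets",
    "overlap_sensitivity_sweep",
]

NodeSets = Sequence[frozenset]


def _node_sets(comms) -> list[frozenset]:
    out = []
    for c in comms:
        ns = c.nodes if isinstance(c, Community) else frozenset(c)
        if not ns:
            raise ValueError("empty community in evaluation set")
        out.append(ns)
    if not out:
        raise ValueError("empty community set")
    return out


def _harmonic(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def jaccard(A: frozenset, B: frozenset) -> float:
    if not A or not B:
        raise ValueError("jaccard of an empty set is undefined")
    return len(A & B) / len(A | B)


def neighborhood_affinity(A: frozenset, B: frozenset) -> float:
    if not A or not B:
        raise ValueError("affinity of an empty set is undefined")
    inter = len(A & B)
    return inter * inter / (len(A) * len(B))


def f_similarity(C_k: frozenset, C_l: frozenset) -> tuple[float, float, float]:
    """Node precision, recall and their harmonic mean for one pair.

    Precision is the fraction of learned nodes that are known, recall the
    fraction of known nodes that are learned.
    """
    if not C_k or not C_l:
        raise ValueError("F-similarity of an empty set is undefined")
    inter = len(C_k & C_l)
    p = inter / len(C_l)
    r = inter / len(C_k)
    return p, r, _harmonic(p, r)


def f_sim(C_k: frozenset, C_l: frozenset) -> float:
    return f_similarity(C_k, C_l)[2]


def qi_prf(K, L, t: float = 0.5) -> tuple[float, float, float]:
    """Thresholded match counting.

    A pair matches at threshold ``t`` when both the learned-node precision
    and the known-node recall reach ``t`` (this package's match criterion).
    Recall is the fraction of known communities with at least one match,
    precision the fraction of learned communities with at least one match.
    """
    K, L = _node_sets(K), _node_sets(L)

    def match(ck: frozenset, cl: frozenset) -> bool:
        inter = len(ck & cl)
        return inter / len(cl) >= t and inter / len(ck) >= t

    recall = sum(any(match(ck, cl) for cl in L) for ck in K) / len(K)
    precision = sum(any(match(ck, cl) for ck in K) for cl in L) / len(L)
    return precision, recall, _harmonic(precision, recall)


def sensitive_prf(
    K, L, sim: Callable[[frozenset, frozenset], float] = f_sim
) -> tuple[float, float, float]:
    """Best-match averaging framework, pluggable in the similarity.

    Recall averages, over known communities, the best similarity to any
    learned community; precision is the mirror image.
    """
    K, L = _node_sets(K), _node_sets(L)
    r = float(np.mean([max(sim(ck, cl) for cl in L) for ck in K]))
    p = float(np.mean([max(sim(ck, cl) for ck in K) for cl in L]))
    return p, r, _harmonic(p, r)


def cmff(K, L) -> tuple[float, float, float]:
    """Community-wise maximum F-similarity F-score."""
    return sensitive_prf(K, L, sim=f_sim)


def _sim_matrix(K: list[frozenset], L: list[frozenset]) -> np.ndarray:
    M = np.zeros((len(K), len(L)))
    for i, ck in enumerate(K):
        for j, cl in enumerate(L):
            M[i, j] = f_sim(ck, cl)
    return M


def fmmf(K, L) -> tuple[float, float, float, list[tuple[int, int, float]]]:
    """Maximum-weight one-to-one matching F-score.

    The bipartite graph between known and learned communities is weighted by
    F-similarity; an exact maximum-weight matching M is found and its total
    weight W gives recall W/|K| and precision W/|L|.  Returns (P, R, F,
    matching) with the matching as (known index, learned index, weight)
    triples sorted by index for reproducibility.
    """
    K, L = _node_sets(K), _node_sets(L)
    M = _sim_matrix(K, L)
    rows, cols = linear_sum_assignment(M, maximize=True)
    matching = sorted(
        (int(i), int(j), float(M[i, j])) for i, j in zip(rows, cols) if M[i, j] > 0
    )
    W = float(sum(w for _, _, w in matching))
    r = W / len(K)
    p = W / len(L)
    return p, r, _harmonic(p, r), matching


def mmr(K, L) -> float:
    """Maximal matching ratio: matching weight over the known-set size."""
    _, r, _, _ = fmmf(K, L)
    return r


def spa_and_unspa(K, L) -> tuple[float, float, float, float, float, float]:
    """Sn, PPV, SPA and their per-community-unweighted (unbiased) variants.

    With t_kl = |C_k ∩ C_l|:
      Sn    = sum_k max_l t_kl / sum_k |C_k|
      PPV   = sum_l max_k t_kl / sum_l sum_k t_kl
      Sn_u  = mean_k max_l t_kl / |C_k|
      PPV_u = mean_l max_k t_kl / |C_l|
    SPA and UnSPA are the geometric means of the respective pairs.
    """
    K, L = _node_sets(K), _node_sets(L)
    T = np.array([[len(ck & cl) for cl in L] for ck in K], dtype=float)
    sn = T.max(axis=1).sum() / sum(len(ck) for ck in K)
    ppv_den = T.sum()
    ppv = 0.0 if ppv_den == 0 else T.max(axis=0).sum() / ppv_den
    sn_u = float(np.mean(T.max(axis=1) / np.array([len(ck) for ck in K])))
    ppv_u = float(np.mean(T.max(axis=0) / np.array([len(cl) for cl in L])))
    return (
        float(sn),
        float(ppv),
        sqrt(sn * ppv),
        sn_u,
        ppv_u,
        sqrt(sn_u * ppv_u),
    )


def cocomplex_edge_pr(
    K, L, scores: Sequence[float] | None = None
) -> list[tuple[float, float, float]]:
    """Precision-recall sweep over co-membership node pairs.

    Positive pairs co-occur in at least one known community; predicted pairs
    co-occur in at least one learned community and carry the maximum score
    of any containing community.  Returns (threshold, precision, recall)
    points in descending-score order; recall is measured against all known
    pairs, including never-predicted ones.
    """
    K = _node_sets(K)
    if scores is None:
        scores = [c.score for c in L]
        if any(s is None for s in scores):
            raise ValueError("learned communities must carry scores")
    L = _node_sets(L)
    known_pairs = {frozenset(p) for ck in K for p in _pairs(ck)}
    pred: dict[frozenset, float] = {}
    for cl, s in zip(L, scores):
        for p in _pairs(cl):
            fp = frozenset(p)
            if fp not in pred or s > pred[fp]:
                pred[fp] = float(s)
    if not pred or not known_pairs:
        return []
    points = []
    items = sorted(pred.items(), key=lambda kv: -kv[1])
    tp = 0
    npred = 0
    i = 0
    while i < len(items):
        thr = items[i][1]
        while i < len(items) and items[i][1] == thr:
            npred += 1
            if items[i][0] in known_pairs:
                tp += 1
            i += 1
        points.append((thr, tp / npred, tp / len(known_pairs)))
    return points


def _pairs(nodes: frozenset):
    ns = sorted(nodes)
    for a in range(len(ns)):
        for b in range(a + 1, len(ns)):
            yield ns[a], ns[b]


@dataclass
class EvalReport:
    qi_precision: float
    qi_recall: float
    qi_f1: float
    fmmf_p: float
    fmmf_r: float
    fmmf: float
    cmff_p: float
    cmff_r: float
    cmff: float
    sn: float
    ppv: float
    spa: float
    sn_u: float
    ppv_u: float
    unspa: float
    mmr: float

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_sets(K, L, qi_t: float = 0.5) -> EvalReport:
    """All scalar measures comparing learned set L against known set K."""
    qp, qr, qf = qi_prf(K, L, t=qi_t)
    fp, fr, ff, _ = fmmf(K, L)
    cp, cr, cf = cmff(K, L)
    sn, ppv, spa, sn_u, ppv_u, unspa = spa_and_unspa(K, L)
    return EvalReport(
        qi_precision=qp,
        qi_recall=qr,
        qi_f1=qf,
        fmmf_p=fp,
        fmmf_r=fr,
        fmmf=ff,
        cmff_p=cp,
        cmff_r=cr,
        cmff=cf,
        sn=sn,
        ppv=ppv,
        spa=spa,
        sn_u=sn_u,
        ppv_u=ppv_u,
        unspa=unspa,
        mmr=fr,
    )


def overlap_sensitivity_sweep(
    K, candidate_sets: dict[float, Sequence], qi_t: float = 0.5
) -> pd.DataFrame:
    """One metrics row per merge-threshold point, for sensitivity analysis."""
    if len(candidate_sets) < 2:
        raise ValueError("need at least two threshold points")
    rows = []
    for thr in sorted(candidate_sets):
        rep = evaluate_sets(K, candidate_sets[thr], qi_t=qi_t)
        rows.append({"threshold": thr, **rep.to_dict()})
    return pd.DataFrame(rows)
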