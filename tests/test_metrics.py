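from itertools import permutations

import numpy as np
import pytest

from commfit import metrics
from commfit.metrics import (
    cmff,
    cocomplex_edge_pr,
    evaluate_sets,
    f_similarity,
    fmmf,
    jaccard,
    mmr,
    neighborhood_affinity,
    overlap_sensitivity_sweep,
    qi_prf,
    sensitive_prf,
    spa_and_unspa,
)


def S(*nodes):
    return frozenset(str(n) for n in nodes)


def random_sets(rng, n_sets, universe=12, max_size=6):
    out = []
    for _ in range(n_sets):
        size = int(rng.integers(2, max_size + 1))
        out.append(frozenset(map(str, rng.choice(universe, size=size, replace=False))))
    return out


def brute_force_matching_weight(K, L):
    """Optimal one-to-one assignment weight by exhaustive permutation."""
    best = 0.0
    small, big, transpose = (K, L, False) if len(K) <= len(L) else (L, K, True)
    for perm in permutations(range(len(big)), len(small)):
        w = sum(
            metrics.f_sim(small[i], big[j]) if not transpose else metrics.f_sim(big[j], small[i])
            for i, j in enumerate(perm)
        )
        best = max(best, w)
    return best


class TestPairSimilarities:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(S(1, 2, 3), S(1, 2, 3), 1.0), (S(1, 2), S(3, 4), 0.0), (S("a", "b", "c"), S("b", "c", "d"), 0.5)],
    )
    def test_jaccard(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    def test_jaccard_empty_errors(self):
        with pytest.raises(ValueError):
            jaccard(frozenset(), S(1))

    @pytest.mark.parametrize(
        "ck,cl,expected",
        [
            (S(1, 2, 3), S(1, 2, 3), (1, 1, 1)),
            (S(1, 2, 3, 4), S(1, 2, 3, 4, 5, 6), (4 / 6, 1.0, 0.8)),
            (S(1, 2), S(3, 4), (0, 0, 0)),
        ],
    )
    def test_f_similarity(self, ck, cl, expected):
        p, r, f = f_similarity(ck, cl)
        assert (p, r, f) == pytest.approx(expected)

    def test_neighborhood_affinity_penalizes_asymmetry(self):
        assert neighborhood_affinity(S(1, 2, 3), S(1, 2, 3, 4, 5, 6)) == pytest.approx(9 / 18)


class TestQiPrf:
    def test_identical_sets(self):
        K = [S(1, 2, 3), S(4, 5, 6)]
        assert qi_prf(K, K) == (1.0, 1.0, 1.0)

    def test_spurious_learned_community(self):
        K = [S(1, 2, 3), S(4, 5, 6)]
        L = K + [S(90, 91, 92)]
        p, r, f = qi_prf(K, L)
        assert r == 1.0 and p == pytest.approx(2 / 3)

    def test_fully_disjoint(self):
        assert qi_prf([S(1, 2, 3)], [S(7, 8, 9)]) == (0.0, 0.0, 0.0)


class TestSensitiveFramework:
    def test_perfect_recall_half_precision(self):
        K = [S(1, 2, 3)]
        L = [S(1, 2, 3), S(7, 8, 9)]
        p, r, f = sensitive_prf(K, L)
        assert (r, p) == (1.0, 0.5)
        assert f == pytest.approx(2 / 3)

    def test_pluggable_similarity_differs_on_asymmetric_overlap(self):
        K = [S(1, 2, 3, 4)]
        L = [S(1, 2, 3, 4, 5, 6, 7, 8)]
        with_f = sensitive_prf(K, L, sim=metrics.f_sim)
        with_j = sensitive_prf(K, L, sim=jaccard)
        assert with_f != with_j


class TestCmff:
    def test_single_pair(self):
        p, r, f = cmff([S(1, 2, 3, 4)], [S(1, 2, 3, 4, 5, 6)])
        assert p == r == pytest.approx(0.8)
        assert f == pytest.approx(0.8)

    def test_splitting_a_known_community_lowers_cmff(self):
        K = [S(1, 2, 3, 4, 5, 6)]
        exact = cmff(K, [S(1, 2, 3, 4, 5, 6)])[2]
        split = cmff(K, [S(1, 2, 3), S(4, 5, 6)])[2]
        assert split < exact == 1.0


class TestFmmf:
    def test_identity(self):
        K = [S(1, 2, 3), S(4, 5, 6)]
        p, r, f, matching = fmmf(K, K)
        assert f == 1.0 and len(matching) == 2

    def test_single_possible_matching(self):
        p, r, f, _ = fmmf([S(1, 2, 3), S(4, 5, 6)], [S(1, 2, 3)])
        assert (p, r) == (1.0, 0.5)
        assert f == pytest.approx(2 / 3)

    def test_matching_weight_equals_brute_force(self):
        """Assignment optimum vs exhaustive permutations on random pairs."""
        rng = np.random.default_rng(2024)
        for _ in range(60):
            K = random_sets(rng, int(rng.integers(1, 7)))
            L = random_sets(rng, int(rng.integers(1, 7)))
            _, r, _, matching = fmmf(K, L)
            got = sum(w for _, _, w in matching)
            assert got == pytest.approx(brute_force_matching_weight(K, L), abs=1e-9)

    def test_redundancy_penalty(self):
        """Duplicating every learned community halves precision but leaves
        recall unchanged (one-to-one matching)."""
        rng = np.random.default_rng(3)
        K = [S(1, 2, 3), S(4, 5, 6, 7), S(8, 9, 10)]
        L = [S(1, 2, 3), S(4, 5, 6)] + random_sets(rng, 2)
        p1, r1, _, _ = fmmf(K, L)
        p2, r2, _, _ = fmmf(K, L + L)
        assert r2 == pytest.approx(r1)
        assert p2 < p1

    def test_split_penalty(self):
        K = [S(1, 2, 3, 4, 5, 6), S(7, 8, 9)]
        exact = fmmf(K, [S(1, 2, 3, 4, 5, 6), S(7, 8, 9)])[2]
        split = fmmf(K, [S(1, 2, 3), S(4, 5, 6), S(7, 8, 9)])[2]
        assert split < exact


class TestMmr:
    def test_mmr_is_fmmf_recall(self):
        rng = np.random.default_rng(4)
        K, L = random_sets(rng, 4), random_sets(rng, 5)
        assert mmr(K, L) == pytest.approx(fmmf(K, L)[1])

    def test_half_matched(self):
        assert mmr([S(1, 2, 3), S(4, 5, 6)], [S(1, 2, 3)]) == pytest.approx(0.5)


class TestSpaUnspa:
    def test_identity_on_disjoint_sets(self):
        K = [S(1, 2, 3), S(4, 5, 6, 7)]
        assert spa_and_unspa(K, K) == pytest.approx((1, 1, 1, 1, 1, 1))

    def test_size_bias_fixture(self):
        """Sn weights big communities more; Sn_u weights all equally.

        Known: {1..6} and {7,8,9}. Learned: the two perfect halves of the
        big community only.  Sn = (6+0... ) hand-computed below.
        """
        K = [S(1, 2, 3, 4, 5, 6), S(7, 8, 9)]
        L = [S(1, 2, 3), S(4, 5, 6)]
        sn, ppv, spa, sn_u, ppv_u, unspa = spa_and_unspa(K, L)
        # Sn: best recall of {1..6} is 3 nodes, of {7,8,9} is 0 -> 3/9
        assert sn == pytest.approx(3 / 9)
        # Sn_u: mean(3/6, 0/3) = 0.25
        assert sn_u == pytest.approx(0.25)
        assert sn != sn_u

    def test_small_community_detector_preferred_by_unbiased_sn(self):
        K = [S(*range(10)), S("a", "b", "c"), S("d", "e", "f")]
        small_detector = [S("a", "b", "c"), S("d", "e", "f")]
        big_partial = [S(0, 1, 2, 3, 4, 5, 6)]
        sn_small = spa_and_unspa(K, small_detector)[0]
        sn_big = spa_and_unspa(K, big_partial)[0]
        snu_small = spa_and_unspa(K, small_detector)[3]
        snu_big = spa_and_unspa(K, big_partial)[3]
        assert sn_big > sn_small  # the bias the unbiased variant removes
        assert snu_small > snu_big

    def test_spurious_nodes_lower_only_unbiased_ppv(self):
        K = [S(1, 2, 3, 4)]
        exact = [S(1, 2, 3, 4)]
        padded = [S(1, 2, 3, 4, "x", "y", "z", "w")]
        ppv_exact, ppv_u_exact = spa_and_unspa(K, exact)[1], spa_and_unspa(K, exact)[4]
        ppv_pad, ppv_u_pad = spa_and_unspa(K, padded)[1], spa_and_unspa(K, padded)[4]
        assert ppv_pad == pytest.approx(ppv_exact)  # PPV ignores non-known nodes
        assert ppv_u_pad < ppv_u_exact


class TestCocomplexEdgePr:
    def test_perfect_prediction_single_point(self):
        K = [S(1, 2, 3)]
        pts = cocomplex_edge_pr(K, K, scores=[1.0])
        assert pts == [(1.0, 1.0, 1.0)]

    def test_partial_coverage_caps_recall(self):
        K = [S(1, 2, 3, 4)]  # 6 pairs
        L = [S(1, 2, 3)]  # 3 of them
        pts = cocomplex_edge_pr(K, L, scores=[0.9])
        assert pts[-1][2] == pytest.approx(0.5)

    def test_spurious_community_lowers_precision(self):
        K = [S(1, 2, 3)]
        clean = cocomplex_edge_pr(K, [S(1, 2, 3)], scores=[0.9])
        noisy = cocomplex_edge_pr(K, [S(1, 2, 3), S(7, 8, 9)], scores=[0.9, 0.8])
        assert noisy[-1][1] < clean[-1][1]

    def test_unscored_learned_set_errors(self):
        from commfit.graph_store import Community

        K = [S(1, 2, 3)]
        c = Community(nodes=S(1, 2, 3), n_c=3, m_c=3)
        with pytest.raises(ValueError, match="scores"):
            cocomplex_edge_pr(K, [c])


class TestEvaluateSets:
    def test_all_ones_on_identical_sets(self):
        K = [S(1, 2, 3), S(4, 5, 6, 7)]
        rep = evaluate_sets(K, K)
        assert all(v == 1.0 for v in rep.to_dict().values())

    def test_all_measures_bounded_and_harmonic_consistent(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            K, L = random_sets(rng, 4), random_sets(rng, 5)
            rep = evaluate_sets(K, L)
            d = rep.to_dict()
            assert all(0 <= v <= 1 for v in d.values())
            for p, r, f in (("qi_precision", "qi_recall", "qi_f1"),
                            ("fmmf_p", "fmmf_r", "fmmf"),
                            ("cmff_p", "cmff_r", "cmff")):
                if d[p] + d[r] > 0:
                    assert d[f] == pytest.approx(2 * d[p] * d[r] / (d[p] + d[r]))
            assert d["spa"] == pytest.approx((d["sn"] * d["ppv"]) ** 0.5)
            assert d["unspa"] == pytest.approx((d["sn_u"] * d["ppv_u"]) ** 0.5)
            assert d["mmr"] == pytest.approx(d["fmmf_r"])

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        K, L = random_sets(rng, 3), random_sets(rng, 4)
        ren = {str(i): f"z{i}" for i in range(12)}
        K2 = [frozenset(ren[n] for n in s) for s in K]
        L2 = [frozenset(ren[n] for n in s) for s in L]
        assert evaluate_sets(K, L).to_dict() == pytest.approx(evaluate_sets(K2, L2).to_dict())


class TestOverlapSweep:
    def test_duplication_affects_fmmf_not_qi_precision(self):
        K = [S(1, 2, 3), S(4, 5, 6)]
        L = [S(1, 2, 3), S(4, 5, 6)]
        table = overlap_sensitivity_sweep(K, {0.5: L, 1.0: L + L})
        dedup = table[table.threshold == 0.5].iloc[0]
        dup = table[table.threshold == 1.0].iloc[0]
        assert dup.fmmf_p == pytest.approx(dedup.fmmf_p / 2)
        assert dup.qi_precision == pytest.approx(dedup.qi_precision)

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            overlap_sensitivity_sweep([S(1, 2, 3)], {0.5: [S(1, 2, 3)]})
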