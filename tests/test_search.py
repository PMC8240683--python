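from math import exp

import numpy as np
import pytest

from commfit import search
from commfit.fitness import DensityScorer
from commfit.graph_store import community_is_connected, graph_from_edges, induced_subgraph
from commfit.search import SearchParams, SeedSpec, accept_step, grow_seed, max_steps_smart, run_search
from commfit.synthetic import make_clique_toy


class TestSelectSeeds:
    def test_all_nodes(self):
        g = graph_from_edges([(str(i), str(i + 1), 1.0) for i in range(4)])
        seeds = search.select_seeds(g, SeedSpec(mode="all_nodes"))
        assert len(seeds) == 5 and all(len(s) == 1 for s in seeds)

    def test_maximal_cliques_of_two_triangles(self):
        graph, _ = make_clique_toy(2, [3, 3])
        seeds = search.select_seeds(graph, SeedSpec(mode="maximal_cliques"))
        assert sorted(len(s) for s in seeds) == [3, 3]

    def test_random_n_reproducible_and_bounded(self):
        g = graph_from_edges([(str(i), str(i + 1), 1.0) for i in range(9)])
        s1 = search.select_seeds(g, SeedSpec(mode="random_n", n_random=4), rng_seed=5)
        s2 = search.select_seeds(g, SeedSpec(mode="random_n", n_random=4), rng_seed=5)
        assert s1 == s2 and len(set(s1)) == 4
        with pytest.raises(ValueError):
            search.select_seeds(g, SeedSpec(mode="random_n", n_random=99))

    def test_known_community_nodes(self):
        graph, truth = make_clique_toy(2, [3, 4])
        seeds = search.select_seeds(
            graph, SeedSpec(mode="known_community_nodes"), known=truth[:1]
        )
        assert {next(iter(s)) for s in seeds} == set(truth[0].nodes)


class TestMaxStepsSmart:
    @pytest.mark.parametrize(
        "sizes,expected",
        [
            ([3, 3, 4, 5, 20], 5),  # Q3=5, IQR=2, fence=8 -> outlier 20 ignored
            ([3, 4, 5], 5),
            ([6, 6, 6, 6], 6),
        ],
    )
    def test_outlier_robust_max(self, sizes, expected):
        from commfit.graph_store import Community

        comms = [
            Community(nodes=frozenset(f"s{i}_{j}" for j in range(s)), n_c=s, m_c=0)
            for i, s in enumerate(sizes)
        ]
        assert max_steps_smart(comms) == expected


class TestAcceptStep:
    def test_equal_scores_always_accepted(self):
        params = SearchParams(heuristic="eps_greedy_isa", T0=1.0, alpha=0.5)
        rng = np.random.default_rng(0)
        accept, T = accept_step(0.7, 0.7, iteration=3, params=params, rng=rng)
        assert accept and T == pytest.approx(1.0 * 0.5**3)

    def test_isa_monte_carlo_matches_closed_form(self):
        """Empirical ISA acceptance for dS=-0.1, T=1 within the 99% binomial
        CI of exp(-0.1)."""
        params = SearchParams(heuristic="eps_greedy_isa", T0=1.0, alpha=1.0)
        rng = np.random.default_rng(123)
        n = 10_000
        hits = sum(accept_step(0.6, 0.5, 0, params, rng)[0] for _ in range(n))
        p = exp(-0.1)
        half = 2.576 * (p * (1 - p) / n) ** 0.5
        assert abs(hits / n - p) <= half

    def test_pseudo_metropolis_constant_rate(self):
        params = SearchParams(heuristic="eps_greedy_pseudo_metropolis", k_accept=0.1)
        rng = np.random.default_rng(7)
        n = 10_000
        hits = sum(accept_step(0.6, 0.5, 0, params, rng)[0] for _ in range(n))
        half = 2.576 * (0.1 * 0.9 / n) ** 0.5
        assert abs(hits / n - 0.1) <= half

    def test_temperature_strictly_decreasing_when_cooling(self):
        params = SearchParams(heuristic="eps_greedy_isa", T0=2.0, alpha=0.5)
        rng = np.random.default_rng(0)
        temps = [accept_step(0.9, 0.9, i, params, rng)[1] for i in range(5)]
        assert all(a > b for a, b in zip(temps, temps[1:]))


def exhaustive_greedy(graph, scorer, seed_node, max_steps):
    """Independent oracle: no sampling caps, full neighbor evaluation.

    First step adds the highest-weight neighbor; later steps the neighbor
    whose addition scores best (lexicographic tie-break); stops on the same
    no-neighbor / score<0.5 rules as the production grower.
    """
    members = {seed_node}
    for step in range(max_steps):
        boundary = sorted(
            {v for u in members for v, _ in graph.neighbors(u)} - members
        )
        if not boundary:
            break
        if step == 0:
            weights = {
                v: max(w for u in members for x, w in graph.neighbors(u) if x == v)
                for v in boundary
            }
            cand = min(boundary, key=lambda v: (-weights[v], v))
        else:
            scores = {
                v: scorer.score_community(induced_subgraph(graph, members | {v}), graph)
                for v in boundary
            }
            cand = min(boundary, key=lambda v: (-scores[v], v))
        members.add(cand)
        if scorer.score_community(induced_subgraph(graph, members), graph) < 0.5:
            members.remove(cand)
            break
    if len(members) < 2:
        return None
    comm = induced_subgraph(graph, members)
    if scorer.score_community(comm, graph) < 0.5:
        return None
    return frozenset(members)


class TestGrowSeed:
    def test_toy_clique_recovered_exactly(self):
        graph, truth = make_clique_toy(3, [4, 5, 6])
        scorer = DensityScorer()
        params = SearchParams(heuristic="eps_greedy", epsilon=0.0, max_steps=10)
        for clique in truth:
            seed = sorted(clique.nodes)[0]
            got = grow_seed(graph, scorer, {seed}, params)
            assert got is not None and got.nodes == clique.nodes

    def test_isolated_seed_returns_none(self):
        g = graph_from_edges([("a", "b", 1.0)])
        g.g.add_node("lonely")
        params = SearchParams(heuristic="eps_greedy", epsilon=0.0, max_steps=5)
        assert grow_seed(g, DensityScorer(), {"lonely"}, params) is None

    def test_matches_exhaustive_greedy_oracle_on_small_graphs(self):
        """eps=0 growth with unlimited sampling caps equals the brute-force
        greedy oracle on random weighted graphs of <= 12 nodes."""
        rng = np.random.default_rng(99)
        scorer = DensityScorer()
        for trial in range(15):
            n = int(rng.integers(5, 13))
            edges = []
            for a in range(n):
                for b in range(a + 1, n):
                    if rng.random() < 0.4:
                        edges.append((f"n{a}", f"n{b}", float(rng.uniform(0.1, 1.0))))
            if not edges:
                continue
            g = graph_from_edges(edges)
            params = SearchParams(
                heuristic="eps_greedy", epsilon=0.0, t1=10**6, t2=10**6, max_steps=n
            )
            for node in sorted(g.nodes)[:4]:
                got = grow_seed(g, scorer, {node}, params)
                want = exhaustive_greedy(g, scorer, node, n)
                assert (got.nodes if got else None) == want

    def test_multi_node_clique_seed_first_step(self):
        graph, truth = make_clique_toy(1, [5])
        params = SearchParams(heuristic="eps_greedy", epsilon=0.0, max_steps=6)
        seed = frozenset(sorted(truth[0].nodes)[:3])
        got = grow_seed(graph, DensityScorer(), seed, params)
        assert got.nodes == truth[0].nodes


class TestRunSearch:
    def test_toy_all_node_seeds_recover_planted_cliques(self):
        graph, truth = make_clique_toy(10, [3, 4, 5, 6, 7, 8, 3, 4, 5, 6])
        seeds = search.select_seeds(graph, SeedSpec(mode="all_nodes"))
        params = SearchParams(heuristic="eps_greedy", epsilon=0.0, max_steps=10)
        found = run_search(graph, DensityScorer(), seeds, params, n_workers=1)
        assert sorted(c.key() for c in found) == sorted(c.key() for c in truth)

    def test_worker_count_invariance(self, planted):
        graph, model = planted["graph"], planted["model"]
        seeds = search.select_seeds(
            graph, SeedSpec(mode="random_n", n_random=12), rng_seed=4
        )
        params = SearchParams(heuristic="eps_greedy_isa", rng_seed=4, max_steps=9)
        r1 = run_search(graph, model, seeds, params, n_workers=1)
        r4 = run_search(graph, model, seeds, params, n_workers=4)
        assert [c.key() for c in r1] == [c.key() for c in r4]

    def test_connectivity_and_score_guarantees(self, planted):
        graph, model = planted["graph"], planted["model"]
        seeds = search.select_seeds(
            graph, SeedSpec(mode="random_n", n_random=15), rng_seed=8
        )
        params = SearchParams(
            heuristic="eps_greedy_pseudo_metropolis", rng_seed=8, max_steps=9
        )
        found = run_search(graph, model, seeds, params, n_workers=1)
        assert found
        for c in found:
            assert community_is_connected(graph, c)
            assert c.score >= 0.5

    def test_duplicates_deduplicated(self):
        graph, truth = make_clique_toy(1, [4])
        seeds = search.select_seeds(graph, SeedSpec(mode="all_nodes"))
        params = SearchParams(heuristic="eps_greedy", epsilon=0.0, max_steps=5)
        found = run_search(graph, DensityScorer(), seeds, params)
        assert len(found) == 1
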