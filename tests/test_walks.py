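import itertools

import networkx as nx
import numpy as np
import pytest

import fitscape as fs
from fitscape.landscape import LandscapeError
from fitscape.walks import DIRECT, INACCESSIBLE, INDIRECT_REQUIRED


@pytest.fixture(scope="module")
def small_rugged():
    """64-genotype rugged landscape (4 letters x 3 sites), complete."""
    spec = fs.SyntheticSpec(
        L=3, alphabet_size=4, seed=23, additive_sd=1.0,
        pairwise_density=0.4, pairwise_sd=1.5, threeway_sites=None,
        lethal_fraction=0.05, missing_fraction=0.0, site_labels=(1, 2, 3),
    )
    ls, _ = fs.generate_landscape(spec)
    return ls, fs.build_graph(ls)


class TestGraph:
    def test_edges_strictly_ascend(self, small_rugged):
        ls, g = small_rugged
        for u, v in g.edges:
            assert g.nodes[v]["fitness"] > g.nodes[u]["fitness"]
            assert fs.hamming_distance(u, v) == 1
        assert nx.is_directed_acyclic_graph(g)

    def test_equal_fitness_no_edge(self):
        ls = fs.FitnessLandscape("A", {"A": 1.0, "C": 1.0}, alphabet="AC",
                                 site_labels=(1,))
        g = fs.build_graph(ls)
        assert g.number_of_edges() == 0

    def test_peaks_match_bruteforce_scan(self, small_rugged):
        ls, g = small_rugged
        peaks = set(fs.find_peaks(g))
        oracle = set()
        for gt, w in ls.entries.items():
            nbs = fs.neighbors(gt, alphabet=ls.alphabet)
            if not any(ls.get(nb, -1) > w for nb in nbs):
                oracle.add(gt)
        assert peaks == oracle

    def test_additive_single_peak(self, smooth_landscape):
        ls, _ = smooth_landscape
        g = fs.build_graph(ls)
        assert len(fs.find_peaks(g)) == 1


class TestFixation:
    def test_correlated_weights_by_gain(self):
        ls = fs.FitnessLandscape("AA", {"AA": 1.0, "CA": 1.1, "AC": 1.3, "CC": 2.0},
                                 alphabet="AC", site_labels=(1, 2))
        g = fs.build_graph(ls)
        probs = fs.fixation_probabilities(g, "AA", fs.CORRELATED)
        assert probs["CA"] == pytest.approx(0.25)
        assert probs["AC"] == pytest.approx(0.75)
        equal = fs.fixation_probabilities(g, "AA", fs.EQUAL)
        assert equal == {"CA": 0.5, "AC": 0.5}
        greedy = fs.fixation_probabilities(g, "AA", fs.GREEDY)
        assert greedy == {"AC": 1.0, "CA": 0.0}

    def test_peak_has_empty_map(self, small_rugged):
        _, g = small_rugged
        peak = fs.find_peaks(g)[0]
        assert fs.fixation_probabilities(g, peak, fs.CORRELATED) == {}


class TestWalks:
    def test_walks_ascend_and_end_at_peaks(self, small_rugged):
        ls, g = small_rugged
        peaks = set(fs.find_peaks(g))
        walks = fs.simulate_walks(g, ls.wt, fs.EQUAL, n=200, seed=1)
        assert len(walks) == 200
        for w in walks:
            fits = [g.nodes[x]["fitness"] for x in w.path]
            assert all(b > a for a, b in zip(fits, fits[1:]))
            assert w.endpoint in peaks

    def test_step_class_bookkeeping(self, small_rugged):
        """#towards - #detour = HD(start, endpoint); classes sum to length."""
        ls, g = small_rugged
        for model in fs.FIXATION_MODELS:
            for w in fs.simulate_walks(g, ls.wt, model, n=100, seed=3):
                assert w.n_towards + w.n_conversion + w.n_detour == w.length
                assert w.n_towards - w.n_detour == fs.hamming_distance(
                    w.path[0], w.endpoint)

    def test_start_at_peak_zero_length(self, small_rugged):
        _, g = small_rugged
        peak = fs.find_peaks(g)[0]
        walks = fs.simulate_walks(g, peak, fs.CORRELATED, n=5, seed=0)
        assert all(w.length == 0 for w in walks)

    def test_greedy_deterministic(self, small_rugged):
        ls, g = small_rugged
        walks = fs.simulate_walks(g, ls.wt, fs.GREEDY, n=20, seed=9)
        assert len({tuple(w.path) for w in walks}) == 1

    def test_selection_strength_orders_walk_length(self, small_rugged):
        """Mean length: greedy <= correlated <= equal."""
        ls, g = small_rugged
        means = {}
        for model in (fs.GREEDY, fs.CORRELATED, fs.EQUAL):
            walks = fs.simulate_walks(g, ls.wt, model, n=400, seed=11)
            means[model] = fs.summarize_walks(walks)["mean_length"]
        assert means[fs.GREEDY] <= means[fs.CORRELATED] <= means[fs.EQUAL]

    def test_endpoint_frequencies_match_markov_absorption(self, small_rugged):
        """Empirical endpoint frequencies vs exact absorption probabilities."""
        ls, g = small_rugged
        model = fs.CORRELATED
        # exact absorption by dynamic programming over the DAG
        order = list(nx.topological_sort(g))[::-1]  # peaks first
        absorb: dict[str, dict[str, float]] = {}
        for node in order:
            probs = fs.fixation_probabilities(g, node, model)
            if not probs:
                absorb[node] = {node: 1.0}
                continue
            acc: dict[str, float] = {}
            for nxt, p in probs.items():
                for peak, q in absorb[nxt].items():
                    acc[peak] = acc.get(peak, 0.0) + p * q
            absorb[node] = acc
        n = 1000
        walks = fs.simulate_walks(g, ls.wt, model, n=n, seed=29)
        freq: dict[str, float] = {}
        for w in walks:
            freq[w.endpoint] = freq.get(w.endpoint, 0.0) + 1 / n
        for peak, p in absorb[ls.wt].items():
            se = max(np.sqrt(p * (1 - p) / n), 1e-3)
            assert abs(freq.get(peak, 0.0) - p) <= 3 * se


class TestAccessibility:
    def test_additive_never_indirect(self, smooth_landscape):
        """Without epistasis a monotone route, when one exists, is direct;
        targets carrying a deleterious allele are outright inaccessible."""
        ls, truth = smooth_landscape
        g = fs.build_graph(ls)
        targets = [t for t, w in ls.entries.items() if w > ls[ls.wt]]
        res = fs.accessibility(g, ls.wt, targets)
        assert INDIRECT_REQUIRED not in res.values()
        all_beneficial = [
            t for t in targets
            if all(truth.singles[(s, aa)] > 0
                   for s, w_aa, aa in zip(ls.site_labels, ls.wt, t) if aa != w_aa)
        ]
        assert all_beneficial and all(res[t] == DIRECT for t in all_beneficial)

    def test_reciprocal_sign_needs_indirect(self):
        entries = {"AA": 1.0, "CA": 0.5, "AC": 0.5, "CC": 2.0,
                   "DA": 1.5, "DC": 1.8, "AD": 0.1, "CD": 0.1, "DD": 0.1}
        ls = fs.FitnessLandscape("AA", entries, alphabet="ACD", site_labels=(1, 2))
        g = fs.build_graph(ls)
        res = fs.accessibility(g, "AA", ["CC"])
        assert res["CC"] == INDIRECT_REQUIRED  # via AA->DA->DC->CC

    def test_matches_exhaustive_path_oracle(self, small_rugged):
        ls, g = small_rugged
        res = fs.accessibility(g, ls.wt, sorted(ls.entries))
        # oracle: BFS over monotone paths, tracking minimal path length
        lengths = nx.single_source_shortest_path_length(g, ls.wt)
        for t, status in res.items():
            if t not in lengths:
                assert status == INACCESSIBLE
            elif lengths[t] == fs.hamming_distance(ls.wt, t):
                assert status == DIRECT
            else:
                assert status == INDIRECT_REQUIRED

    def test_indirect_superset_of_direct(self, small_rugged):
        """Allowing indirect paths only adds reachable targets."""
        ls, g = small_rugged
        targets = sorted(ls.entries)
        res = fs.accessibility(g, ls.wt, targets)
        reachable = {t for t, s in res.items() if s != INACCESSIBLE}
        direct = {t for t, s in res.items() if s == DIRECT}
        assert direct <= reachable

    def test_genetic_code_restricts_accessibility(self):
        spec = fs.SyntheticSpec(
            L=2, alphabet_size=20, seed=31, pairwise_density=0.2,
            pairwise_sd=1.0, threeway_sites=None, lethal_fraction=0.1,
            missing_fraction=0.0, site_labels=(1, 2),
        )
        ls, _ = fs.generate_landscape(spec)
        g_full = fs.build_graph(ls)
        adj = fs.genetic_code_adjacency()
        g_code = fs.build_graph(ls, adj)
        targets = [t for t, w in ls.entries.items() if w > 1]
        res_full = fs.accessibility(g_full, ls.wt, targets)
        res_code = fs.accessibility(g_code, ls.wt, targets, distance="genetic",
                                    adjacency=adj)
        reach_full = {t for t, s in res_full.items() if s != INACCESSIBLE}
        reach_code = {t for t, s in res_code.items() if s != INACCESSIBLE}
        assert reach_code <= reach_full


class TestBasinsAndEntropy:
    def test_additive_single_basin(self, smooth_landscape):
        ls, _ = smooth_landscape
        g = fs.build_graph(ls)
        basins = fs.greedy_basins(g)
        assert len(basins.basins) == 1
        assert sum(basins.sizes.values()) == g.number_of_nodes()

    def test_basins_partition_nodes(self, small_rugged):
        ls, g = small_rugged
        basins = fs.greedy_basins(g)
        all_nodes = set()
        for s in basins.basins.values():
            assert not (all_nodes & s)
            all_nodes |= s
        assert all_nodes == set(g.nodes)
        assert set(basins.basins) == set(fs.find_peaks(g))

    def test_entropy_bounds(self, small_rugged):
        ls, g = small_rugged
        ent = fs.outcome_entropy(g, ls.wt, fs.EQUAL, n=500, seed=2)
        n_peaks = len(fs.find_peaks(g))
        assert 0.0 <= ent <= np.log(n_peaks) + 1e-12

    def test_single_peak_entropy_zero(self, smooth_landscape):
        ls, _ = smooth_landscape
        g = fs.build_graph(ls)
        assert fs.outcome_entropy(g, ls.wt, fs.CORRELATED, n=100, seed=0) == 0.0

    def test_two_equal_peaks_give_ln2(self):
        # symmetric 1-site landscape with two equally attractive peaks
        ls = fs.FitnessLandscape("A", {"A": 1.0, "C": 2.0, "D": 2.0},
                                 alphabet="ACD", site_labels=(1,))
        g = fs.build_graph(ls)
        ent = fs.outcome_entropy(g, "A", fs.EQUAL, n=4000, seed=7)
        assert ent == pytest.approx(np.log(2), abs=0.01)
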