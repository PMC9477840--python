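"""Containers, verified-network construction, and census statistics."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

import saomnet as sn
from saomnet.network import TRIAD_CLASSES

from conftest import random_net


def net_from_arcs(n, arcs, labels=None):
    x = np.zeros((n, n), dtype=np.int8)
    for i, j in arcs:
        x[i, j] = 1
    return sn.DirectedNetwork(x, labels or [])


class TestDirectedNetwork:
    def test_rejects_self_ties_and_nonbinary(self):
        x = np.eye(3, dtype=int)
        with pytest.raises(ValueError, match="self-ties"):
            sn.DirectedNetwork(x)
        with pytest.raises(ValueError, match="0 or 1"):
            sn.DirectedNetwork(np.full((3, 3), 2))

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            sn.DirectedNetwork(np.zeros((1, 1)))


class TestVerifiedNetwork:
    def test_mutual_assent_requires_both_reports(self):
        giver = net_from_arcs(3, [(0, 1), (1, 2)])
        receiver = net_from_arcs(3, [(0, 1)])
        v = sn.build_verified_network(giver, receiver)
        assert v.ties[0, 1] == 1
        assert v.ties[1, 2] == 0  # giver-only report is dropped

    def test_absent_actor_takes_unilateral_report(self):
        labels = ["a", "b", "c"]
        giver = net_from_arcs(3, [(0, 1), (0, 2)], labels)
        receiver = net_from_arcs(3, [], labels)
        v = sn.build_verified_network(giver, receiver, absent={"b"})
        # b is absent: tie a->b follows a's giving report
        assert v.ties[0, 1] == 1
        # c is present and did not confirm receiving: a->c dropped
        assert v.ties[0, 2] == 0

    def test_both_absent_coded_zero(self):
        labels = ["a", "b", "c"]
        giver = net_from_arcs(3, [(0, 1)], labels)
        receiver = net_from_arcs(3, [(0, 1)], labels)
        v = sn.build_verified_network(giver, receiver, absent={"a", "b"})
        assert v.ties[0, 1] == 0

    def test_arcs_subset_of_union_rule(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g, r = random_net(7, rng), random_net(7, rng)
            v = sn.build_verified_network(g, r)
            core = g.ties & r.ties
            assert (v.ties == core).all()  # no absent actors: pure intersection


class TestPreprocessing:
    def test_zero_variance_covariate_rejected(self, village8):
        from dataclasses import replace
        bad = dict(village8.actor_covariates)
        bad["age"] = sn.ActorCovariate("age", np.full(8, 5.0))
        v = replace(village8, actor_covariates=bad)
        with pytest.raises(ValueError, match="age"):
            sn.preprocess_covariates(v)

    def test_distance_log_and_zscores(self):
        village, _ = sn.generate_village(
            sn.VillageRecipe(n=20, households=6, burnin_rate=20.0), seed=0
        )
        d = village.dyad_covariates["distance"].values
        assert d.max() < 15  # log-metres, not metres
        assert d.min() == 0.0  # within-household ln(0 + 1)
        for name in ("household_wealth", "age", "bmi", "melanin", "household_size"):
            vals = village.actor_covariates[name].values
            assert abs(vals.mean()) < 1e-10 and abs(vals.std() - 1) < 1e-10

    def test_negative_distance_rejected(self, village8):
        from dataclasses import replace
        bad = dict(village8.dyad_covariates)
        m = -np.ones((8, 8)) * 1000
        np.fill_diagonal(m, 0)
        bad["distance"] = sn.DyadCovariate("distance", m, symmetric=True)
        v = replace(village8, dyad_covariates=bad)
        with pytest.raises(ValueError, match="non-negative"):
            sn.preprocess_covariates(v)

    def test_relative_wealth_rank_is_directed_rank_difference(self):
        village, _ = sn.generate_village(
            sn.VillageRecipe(n=20, households=6, burnin_rate=20.0), seed=1
        )
        rr = village.dyad_covariates["relative_wealth_rank"].values
        assert np.allclose(rr, -rr.T)
        H = village.households.count
        assert rr.max() <= H - 1 and rr.min() >= -(H - 1)


class TestDescriptives:
    def test_complete_digraph(self):
        n = 5
        x = 1 - np.eye(n, dtype=np.int8)
        net = sn.DirectedNetwork(x)
        assert sn.density(net) == 1.0
        assert sn.reciprocity_proportion(net) == 1.0
        assert sn.transitivity_weak(net) == 1.0

    def test_single_arc(self):
        net = net_from_arcs(3, [(0, 1)])
        assert sn.reciprocity_proportion(net) == 0.0

    def test_empty_network_warns_nan(self):
        net = sn.DirectedNetwork(np.zeros((4, 4), dtype=np.int8))
        with pytest.warns(UserWarning):
            assert math.isnan(sn.reciprocity_proportion(net))

    def test_symmetrised_graph_fully_reciprocal(self):
        rng = np.random.default_rng(5)
        net = random_net(9, rng)
        sym = sn.DirectedNetwork(net.ties | net.ties.T)
        assert sn.reciprocity_proportion(sym) == 1.0

    def test_population_sd(self):
        net = net_from_arcs(3, [(0, 1), (0, 2), (1, 2)])
        s = sn.degree_summaries(net)
        assert s["mean_degree"] == pytest.approx(1.0)
        # out-degrees (2, 1, 0): population sd = sqrt(2/3)
        assert s["sd_out"] == pytest.approx(np.sqrt(2 / 3))


class TestTriadCensus:
    def test_empty_graph_all_null(self):
        net = sn.DirectedNetwork(np.zeros((5, 5), dtype=np.int8))
        c = sn.triad_census(net)
        assert c["003"] == 10 and sum(c.values()) == 10

    def test_requires_three_actors(self):
        with pytest.raises(ValueError):
            sn.triad_census(sn.DirectedNetwork(np.zeros((2, 2), dtype=np.int8)))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_networkx_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(int(rng.integers(4, 11)), rng)
        mine = sn.triad_census(net)
        ref = nx.triadic_census(nx.from_numpy_array(net.ties, create_using=nx.DiGraph))
        assert mine == {k: ref[k] for k in mine}
        assert sum(mine.values()) == math.comb(net.n, 3)


class TestCliqueCensus:
    def test_empty_graph_singletons(self):
        net = sn.DirectedNetwork(np.zeros((4, 4), dtype=np.int8))
        assert sn.clique_census(net) == {1: 4}

    def test_mutual_triangle_plus_isolate(self):
        net = net_from_arcs(4, [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)])
        assert sn.clique_census(net) == {1: 1, 3: 1}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_subset_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_net(8, rng)
        mutual = (net.ties & net.ties.T).astype(bool)

        def is_clique(s):
            return all(mutual[a, b] for a, b in itertools.combinations(s, 2))

        cliques = [set(s) for k in range(1, 9)
                   for s in itertools.combinations(range(8), k) if is_clique(s)]
        maximal = [s for s in cliques if not any(s < t for t in cliques)]
        expected = {}
        for s in maximal:
            expected[len(s)] = expected.get(len(s), 0) + 1
        assert sn.clique_census(net) == expected
        covered = set().union(*maximal)
        assert covered == set(range(8))


class TestGeodesics:
    def test_complete_digraph_all_distance_one(self):
        net = sn.DirectedNetwork(1 - np.eye(4, dtype=np.int8))
        d = sn.geodesic_distribution(net)
        assert d["1"] == 12 and d["inf"] == 0

    def test_directed_chain(self):
        net = net_from_arcs(3, [(0, 1), (1, 2)])
        d = sn.geodesic_distribution(net)
        assert d["1"] == 2 and d["2"] == 1 and d["inf"] == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(10, rng, p=0.15)
        d = sn.geodesic_distribution(net)
        # brute-force BFS per source
        from collections import deque
        counts = {}
        for s in range(10):
            dist = {s: 0}
            q = deque([s])
            while q:
                u = q.popleft()
                for v in np.nonzero(net.ties[u])[0]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        q.append(v)
            for t in range(10):
                if t == s:
                    continue
                k = dist.get(t, math.inf)
                key = str(k) if k <= 5 else "inf"
                counts[key] = counts.get(key, 0) + 1
        for k in d:
            assert d[k] == counts.get(k, 0)
        assert sum(d.values()) == 90


class TestKinStatistics:
    def test_consanguineous_bins_sum_to_arcs(self, village8):
        rng = np.random.default_rng(2)
        net = random_net(8, rng)
        rel_values = np.random.default_rng(0).choice([0.0, 0.125, 0.25, 0.5], (8, 8))
        rel_values = np.triu(rel_values, 1)
        rel_values = rel_values + rel_values.T
        rel = sn.DyadCovariate("consanguineal", rel_values, symmetric=True)
        d = sn.consanguineous_tie_distribution(net, rel)
        assert sum(d.values()) == net.arc_count
        # direct per-arc tally oracle
        for v, c in d.items():
            src, dst = np.nonzero(net.ties)
            assert c == int(sum(abs(rel_values[i, j] - v) <= 1e-9
                                for i, j in zip(src, dst)))

    def test_relatedness_out_of_range_rejected(self):
        net = net_from_arcs(3, [(0, 1)])
        rel = sn.DyadCovariate("consanguineal", np.full((3, 3), 1.5), symmetric=True)
        with pytest.raises(ValueError):
            sn.consanguineous_tie_distribution(net, rel)

    def test_graph_correlation_extremes_and_symmetry(self):
        rng = np.random.default_rng(3)
        a = random_net(6, rng)
        assert sn.graph_correlation(a, a) == pytest.approx(1.0)
        comp = sn.DirectedNetwork((1 - a.ties) - np.diag(np.diagonal(1 - a.ties)))
        assert sn.graph_correlation(a, comp) == pytest.approx(-1.0)
        b = random_net(6, rng)
        assert sn.graph_correlation(a, b) == pytest.approx(sn.graph_correlation(b, a))
        # relabeling both graphs together leaves the correlation unchanged
        perm = rng.permutation(6)
        ap = sn.DirectedNetwork(a.ties[np.ix_(perm, perm)])
        bp = sn.DirectedNetwork(b.ties[np.ix_(perm, perm)])
        assert sn.graph_correlation(ap, bp) == pytest.approx(sn.graph_correlation(a, b))

    def test_kin_triad_composition_extremes(self):
        net = net_from_arcs(3, [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)])
        allkin = sn.DyadCovariate("consanguineal", np.full((3, 3), 0.5), symmetric=True)
        nokin = sn.DyadCovariate("affinal", np.zeros((3, 3)), symmetric=True)
        comp = sn.kin_triad_composition(net, allkin, nokin, 0.125, classes=("300",))
        assert comp["300"] == (1, 1)
        comp0 = sn.kin_triad_composition(net, nokin, nokin, 0.125, classes=("300",))
        assert comp0["300"] == (0, 1)

    def test_triad_classes_complete(self):
        assert len(TRIAD_CLASSES) == 16
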