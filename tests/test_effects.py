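"""Effects library: statistics, change statistics, and specifications.

The naive oracle below evaluates every statistic by literal summation over
actor tuples, independently of the vectorised implementations.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import saomnet as sn
from saomnet.effects import NetworkState

from conftest import make_random_village, random_net


# ---------------------------------------------------------------------------
# independent naive statistic oracle (literal formula evaluation)
# ---------------------------------------------------------------------------


def naive_statistic(spec, village, x, i):
    n = x.shape[0]
    others = [j for j in range(n) if j != i]
    s = spec.shortname
    if s in ("X", "XRecip"):
        w = village.dyad_covariates[spec.covariates[0]].values
    if s in ("alter", "ego", "same", "similarity"):
        v = village.actor_covariates[spec.covariates[0]].values
    if s == "outdegree":
        return sum(x[i, j] for j in others)
    if s == "recip":
        return sum(x[i, j] * x[j, i] for j in others)
    if s == "X":
        return sum(x[i, j] * w[i, j] for j in others)
    if s == "XRecip":
        return sum(x[i, j] * x[j, i] * w[i, j] for j in others)
    if s == "alter":
        return sum(x[i, j] * v[j] for j in others)
    if s == "ego":
        return v[i] * sum(x[i, j] for j in others)
    if s == "same":
        return sum(x[i, j] * (v[i] == v[j]) for j in others)
    if s == "similarity":
        rng_v = v.max() - v.min()
        sim = 1 - np.abs(v[:, None] - v[None, :]) / rng_v
        sim_mean = np.mean([sim[a, b] for a in range(n) for b in range(n) if a != b])
        return sum(x[i, j] * (sim[i, j] - sim_mean) for j in others)
    if s == "outAct":
        return sum(x[i, j] for j in others) ** 2
    if s == "inPop":
        return sum(x[i, j] * sum(x[h, j] for h in range(n)) for j in others)
    if s == "outPop":
        return sum(x[i, j] * sum(x[j, h] for h in range(n)) for j in others)
    if s == "transTrip":
        return sum(x[i, j] * x[i, h] * x[h, j]
                   for j in others for h in others if h != j)
    if s == "transRecTrip":
        return sum(x[i, j] * x[j, i] * x[i, h] * x[h, j]
                   for j in others for h in others if h != j)
    if s == "threeCycle":
        return sum(x[i, j] * x[j, h] * x[h, i]
                   for j in others for h in others if h != j)
    if s == "denseTriads":
        count = 0
        for j, h in itertools.combinations(others, 2):
            if (x[i, j] and x[j, i] and x[i, h] and x[h, i]
                    and x[j, h] and x[h, j]):
                count += 1
        return count
    if s == "transTripJump":
        hh = village.households.ids
        return sum(
            x[i, j] * x[i, h] * x[h, j]
            for j in others for h in others
            if h != j and hh[h] == hh[i] and hh[j] != hh[i]
        )
    if s == "sharedPop":
        total = 0
        for h in others:
            shared = sum(
                1 for j in range(n)
                if j not in (i, h) and x[i, j] and x[h, j]
            )
            total += shared * (shared - 1) // 2
        return total
    raise NotImplementedError(s)


@pytest.fixture(scope="module")
def comprehensive():
    village = make_random_village(7, seed=11)
    ef = sn.build_specification("networked_comprehensive", village)
    return ef.village, ef  # ef.village carries the derived interaction matrices


class TestStatistics:
    def test_reciprocity_on_mutual_dyad(self, comprehensive):
        village, ef = comprehensive
        x = np.zeros((7, 7))
        x[0, 1] = x[1, 0] = 1
        st = NetworkState(x)
        k = ef.names.index("Reciprocity")
        assert ef.statistic(st, k, 0) == 1.0

    def test_transitive_triplet_single_triad(self, comprehensive):
        village, ef = comprehensive
        # i -> h -> j and i -> j: exactly one transitive triplet for i
        x = np.zeros((7, 7))
        i, h, j = 0, 1, 2
        x[i, h] = x[h, j] = x[i, j] = 1
        st = NetworkState(x)
        k = ef.names.index("Transitive Triplets")
        assert ef.statistic(st, k, i) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_every_statistic_matches_naive_oracle(self, comprehensive, seed):
        village, ef = comprehensive
        rng = np.random.default_rng(seed)
        net = random_net(7, rng)
        st = NetworkState(net.ties)
        i = int(rng.integers(0, 7))
        for k, spec in enumerate(ef.effects):
            got = ef.statistic(st, k, i)
            want = naive_statistic(spec, village, net.ties.astype(float), i)
            assert got == pytest.approx(want, abs=1e-9), spec.name

    def test_structural_statistics_relabeling_invariant(self, comprehensive):
        village, ef = comprehensive
        rng = np.random.default_rng(4)
        net = random_net(7, rng)
        perm = rng.permutation(7)
        xp = net.ties[np.ix_(perm, perm)]
        # relabel household assignment along with the adjacency
        from dataclasses import replace
        hh = village.households.ids[perm]
        vil_p = replace(village, households=sn.HouseholdAssignment(hh))
        ef_p = sn.build_specification("networked_comprehensive", vil_p)
        st, st_p = NetworkState(net.ties), NetworkState(xp)
        for k, spec in enumerate(ef.effects):
            if spec.kind != "structural":
                continue
            for new_i, old_i in enumerate(perm):
                assert ef_p.statistic(st_p, k, new_i) == pytest.approx(
                    ef.statistic(st, k, old_i)
                ), spec.name


class TestChangeStatistics:
    def test_reciprocity_add_reciprocating_tie(self, comprehensive):
        village, ef = comprehensive
        x = np.zeros((7, 7))
        x[1, 0] = 1
        st = NetworkState(x)
        k = ef.names.index("Reciprocity")
        assert ef.change_statistic(st, k, 0, 1) == 1.0

    def test_outdegree_drop_existing_tie(self, comprehensive):
        village, ef = comprehensive
        x = np.zeros((7, 7))
        x[0, 1] = 1
        st = NetworkState(x)
        k = ef.names.index("Out-degree")
        assert ef.change_statistic(st, k, 0, 1) == -1.0

    def test_self_toggle_rejected(self, comprehensive):
        village, ef = comprehensive
        st = NetworkState(np.zeros((7, 7)))
        with pytest.raises(ValueError):
            ef.change_statistic(st, 0, 2, 2)

    @pytest.mark.parametrize("seed", range(25))
    def test_delta_equals_statistic_difference(self, comprehensive, seed):
        """The module's central property: local bookkeeping == recompute."""
        village, ef = comprehensive
        rng = np.random.default_rng(1000 + seed)
        net = random_net(7, rng)
        st = NetworkState(net.ties)
        i, j = rng.choice(7, size=2, replace=False)
        before = ef.statistics_actor(st, int(i))
        delta = ef.change_matrix(st, int(i))[:, int(j)]
        st2 = st.copy()
        st2.toggle(int(i), int(j))
        after = ef.statistics_actor(st2, int(i))
        np.testing.assert_allclose(delta, after - before, atol=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20), density=st.floats(0.05, 0.9))
    def test_delta_equivalence_property(self, comprehensive, seed, density):
        """Hypothesis sweep of the same equivalence across graph densities."""
        village, ef = comprehensive
        rng = np.random.default_rng(seed)
        net = random_net(7, rng, p=density)
        st_ = NetworkState(net.ties)
        i, j = rng.choice(7, size=2, replace=False)
        before = ef.statistics_actor(st_, int(i))
        delta = ef.change_matrix(st_, int(i))[:, int(j)]
        st_.toggle(int(i), int(j))
        after = ef.statistics_actor(st_, int(i))
        np.testing.assert_allclose(delta, after - before, atol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_toggle_antisymmetry(self, comprehensive, seed):
        village, ef = comprehensive
        rng = np.random.default_rng(seed)
        net = random_net(7, rng)
        st = NetworkState(net.ties)
        i, j = rng.choice(7, size=2, replace=False)
        fwd = ef.change_matrix(st, int(i))[:, int(j)]
        st.toggle(int(i), int(j))
        back = ef.change_matrix(st, int(i))[:, int(j)]
        np.testing.assert_allclose(fwd, -back, atol=1e-9)

    def test_evaluation_gain_is_dot_product(self, comprehensive):
        village, ef = comprehensive
        rng = np.random.default_rng(9)
        ef.beta = rng.normal(0, 0.5, ef.L)
        net = random_net(7, rng)
        st = NetworkState(net.ties)
        for i in range(7):
            delta = ef.change_matrix(st, i)
            gains = ef.gain_vector(st, i)
            for j in range(7):
                if j == i:
                    assert gains[j] == -np.inf
                else:
                    assert gains[j] == pytest.approx(ef.beta @ delta[:, j])
        ef.beta = np.zeros(ef.L)

    def test_zero_beta_zero_gain(self, comprehensive):
        village, ef = comprehensive
        ef.beta = np.zeros(ef.L)
        st = NetworkState(random_net(7, np.random.default_rng(0)).ties)
        assert ef.evaluation_gain(st, 0, 1) == 0.0


class TestSpecifications:
    def test_effect_counts(self, village8):
        assert sn.build_specification("conventional", village8).L == 5
        assert sn.build_specification("extended", village8).L == 30
        assert sn.build_specification("networked_limited", village8).L == 33
        assert sn.build_specification("networked_comprehensive", village8).L == 39

    def test_unknown_name_lists_valid(self, village8):
        with pytest.raises(ValueError, match="conventional"):
            sn.build_specification("bogus", village8)

    def test_nested_prefixes(self, village8):
        lim = sn.build_specification("networked_limited", village8).names
        comp = sn.build_specification("networked_comprehensive", village8).names
        ext = sn.build_specification("extended", village8).names
        assert comp[:33] == lim and lim[:30] == ext

    def test_interaction_matrices_are_elementwise_products(self, village8):
        ef = sn.build_specification("extended", village8)
        dcov = ef.village.dyad_covariates
        np.testing.assert_allclose(
            dcov["cons_x_distance"].values,
            dcov["consanguineal"].values * dcov["distance"].values,
        )

    def test_missing_covariate_is_hard_error(self, village8):
        from dataclasses import replace
        bad = {k: v for k, v in village8.dyad_covariates.items() if k != "affinal"}
        v = replace(village8, dyad_covariates=bad)
        with pytest.raises(KeyError, match="affinal"):
            sn.build_specification("conventional", v)

    def test_specs_satisfy_invariants(self, village8):
        for name in sn.SPECIFICATION_NAMES:
            ef = sn.build_specification(name, village8)
            assert len(set(ef.names)) == ef.L
            for spec in ef.effects:
                if spec.kind == "structural":
                    assert not spec.covariates
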