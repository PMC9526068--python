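"""Coalescent simulator: determinism, per-tree identities, Newick output,
and cross-validation against an independent simulator (msprime)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coalratios import mean as exact_mean
from coalratios.scalars import UNDEFINED
from coalratios.simulate import (CoalescentTree, empirical_ratio_moments,
                                 replicate_rng, sample_statistics,
                                 simulate_tree, tree_statistics, write_newick)
from coalratios.statistics import B, E, H, I, L, T


class TestSimulateTree:
    def test_same_seed_same_tree(self):
        t1 = simulate_tree(12, np.random.default_rng(7))
        t2 = simulate_tree(12, np.random.default_rng(7))
        assert np.array_equal(t1.times, t2.times)
        assert t1.merges == t2.merges

    def test_n2_forced_topology(self):
        tree = simulate_tree(2, np.random.default_rng(0))
        s = tree_statistics(tree)
        assert tree.merges == ((1, 2),)
        assert s.H == tree.time(2)
        assert s.L == 2 * tree.time(2)
        assert s.E == 2 * tree.time(2) and s.I == 0.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            simulate_tree(1, np.random.default_rng(0))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(n=st.integers(2, 40), seed=st.integers(0, 10 ** 6))
    def test_per_tree_identities(self, n, seed):
        tree = simulate_tree(n, np.random.default_rng(seed))
        s = tree_statistics(tree, basal_small_n=True)
        ks = np.arange(n, 1, -1)
        assert s.H == pytest.approx(np.sum(tree.times), abs=1e-12)
        assert s.L == pytest.approx(float(ks @ tree.times), abs=1e-12)
        assert s.I == pytest.approx(s.L - s.E, abs=1e-12)
        assert s.H == pytest.approx(tree.root_age, abs=1e-12)
        # the root has exactly two children, and node ages are nondecreasing
        assert len(tree.merges[-1]) == 2
        internal_ages = tree.node_ages[n:]
        assert np.all(np.diff(internal_ages) >= 0)
        assert s.B >= 0 and s.E >= 0

    def test_coalescence_time_means(self):
        # sample means of T_k recover 2/(k(k-1)) at 4 SE
        n, reps = 10, 20000
        s = sample_statistics(n, reps, seed=5)
        for k in range(2, n + 1):
            col = s.T[:, k - 2]
            se = col.std(ddof=1) / np.sqrt(reps)
            assert abs(col.mean() - 2 / (k * (k - 1))) < 4 * se


class TestTreeStatistics:
    def _tree3(self):
        return CoalescentTree(n=3, times=np.array([0.2, 0.5]),
                              merges=((1, 2), (4, 3)),
                              node_ages=np.array([0, 0, 0, 0.2, 0.7]))

    def test_hand_computed_n3(self):
        s = tree_statistics(self._tree3())
        assert (s.H, s.L, s.E, s.I) == (pytest.approx(0.7), pytest.approx(1.6),
                                        pytest.approx(1.1), pytest.approx(0.5))
        assert s.B is UNDEFINED

    def test_basal_opt_in_small_n(self):
        s = tree_statistics(self._tree3(), basal_small_n=True)
        # root children: the first cherry (age 0.2) and leaf 3 (age 0)
        assert s.B == pytest.approx(0.5 * (0.5 + 0.7))

    def test_hand_computed_n4(self):
        tree = CoalescentTree(n=4, times=np.array([0.1, 0.2, 0.3]),
                              merges=((1, 2), (3, 4), (5, 6)),
                              node_ages=np.array([0, 0, 0, 0, 0.1, 0.3, 0.6]))
        s = tree_statistics(tree)
        assert (s.H, s.L) == (pytest.approx(0.6), pytest.approx(1.6))
        assert (s.E, s.I) == (pytest.approx(0.8), pytest.approx(0.8))
        assert s.B == pytest.approx(0.4)  # basal branches 0.5 and 0.3

    def test_malformed_tree_rejected(self):
        with pytest.raises(ValueError):
            CoalescentTree(n=4, times=np.array([0.1]), merges=((1, 2),),
                           node_ages=np.zeros(7))

    def test_bundle_value_accessor(self):
        s = tree_statistics(self._tree3())
        assert s.value(T(3)) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            s.value(B)
        with pytest.raises(ValueError):
            s.value(T(4))


class TestEmpiricalMoments:
    def test_h_over_l_at_n2_is_half_exactly(self):
        em = empirical_ratio_moments(H, L, n=2, reps=1000, seed=3)
        assert em.mean == 0.5 and em.variance == 0.0

    def test_reproducible_under_fixed_seed(self):
        a = empirical_ratio_moments(E, H, n=12, reps=400, seed=9)
        b = empirical_ratio_moments(E, H, n=12, reps=400, seed=9)
        assert a == b

    def test_counter_based_substreams_allow_chunking(self):
        # replicate r is fully determined by (seed, n, r)
        s = sample_statistics(6, 50, seed=11)
        tree = simulate_tree(6, replicate_rng(11, 6, 37))
        assert tree_statistics(tree).H == s.H[37]

    def test_external_length_mean_recovered(self, mc_samples_small):
        s = mc_samples_small
        se = s.E.std(ddof=1) / np.sqrt(s.reps)
        assert abs(s.E.mean() - 2.0) < 4 * se

    def test_input_validation(self):
        with pytest.raises(ValueError):
            empirical_ratio_moments(E, E, n=5, reps=100, seed=0)
        with pytest.raises(ValueError):
            empirical_ratio_moments(H, L, n=5, reps=1, seed=0)
        with pytest.raises(ValueError):
            empirical_ratio_moments(B, H, n=3, reps=100, seed=0)


class TestNewick:
    def test_n2_format(self):
        tree = CoalescentTree(n=2, times=np.array([0.5]), merges=((1, 2),),
                              node_ages=np.array([0, 0, 0.5]))
        assert write_newick(tree) == "(1:0.5,2:0.5);"

    @pytest.mark.parametrize("n, seed", [(2, 0), (5, 1), (17, 2)])
    def test_round_trip_with_dendropy(self, n, seed):
        dendropy = pytest.importorskip("dendropy")
        tree = simulate_tree(n, np.random.default_rng(seed))
        s = tree_statistics(tree, basal_small_n=True)
        parsed = dendropy.Tree.get(data=write_newick(tree), schema="newick")
        assert len(parsed.leaf_nodes()) == n
        total = sum(e.length for e in parsed.edges() if e.length is not None)
        assert total == pytest.approx(s.L, rel=1e-9)


class TestAgainstIndependentSimulator:
    def test_height_and_length_match_msprime(self):
        msprime = pytest.importorskip("msprime")
        n, reps = 8, 3000
        hs, ls = np.empty(reps), np.empty(reps)
        sims = msprime.sim_ancestry(samples=n, ploidy=1, population_size=1,
                                    num_replicates=reps, random_seed=99)
        for i, ts in enumerate(sims):
            tree = ts.first()
            hs[i] = tree.time(tree.root)
            ls[i] = tree.total_branch_length
        ours = sample_statistics(n, reps, seed=99)
        for ms_col, our_col, stat in ((hs, ours.H, H), (ls, ours.L, L)):
            exact = float(exact_mean(stat, n))
            for col in (ms_col, our_col):
                se = col.std(ddof=1) / np.sqrt(reps)
                assert abs(col.mean() - exact) < 4 * se
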