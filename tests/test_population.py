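"""Forward one-generation dynamics, transition matrices, genealogy traces."""

import math

import numpy as np
import pytest
from scipy import stats

import asymcoal as ac
from asymcoal.partitions import MassPartition, Partition, all_partitions
from asymcoal.population import (
    DeterministicFrequency,
    DiscreteFrequency,
    DiscreteOffspring,
    UniformFrequency,
    ac_increment,
    ac_transition_matrix,
    awf_increment,
    awf_transition_matrix,
    distinct_power_sum_batch,
    pair_coalescence_probability,
    simulate_genealogy,
)


class TestDistinctPowerSum:
    def test_matches_explicit_enumeration(self, rng):
        # independent brute force over ordered index tuples
        x = rng.random((3, 5))
        for exps in [(2,), (2, 2), (3, 1), (2, 2, 1)]:
            cols = [x**e for e in exps]
            got = distinct_power_sum_batch(cols)
            j = len(exps)
            import itertools

            want = np.zeros(3)
            for idx in itertools.permutations(range(5), j):
                want += np.prod(
                    [x[:, i] ** e for i, e in zip(idx, exps)], axis=0
                )
            assert np.allclose(got, want, atol=1e-12)


class TestIncrements:
    def test_one_hot_eta_always_full_merge(self, rng):
        eta = np.array([1.0, 0.0, 0.0])
        for _ in range(20):
            assert len(awf_increment(eta, 4, rng)) == 1

    def test_all_ones_offspring_always_singletons(self, rng):
        xi = np.ones(6, dtype=int)
        for _ in range(20):
            assert ac_increment(xi, 4, rng).is_singletons()

    def test_two_zero_offspring_merges_both(self, rng):
        assert len(ac_increment(np.array([2, 0]), 2, rng)) == 1

    def test_insufficient_slots_rejected(self, rng):
        with pytest.raises(ValueError):
            ac_increment(np.array([1, 1]), 3, rng)

    def test_invalid_eta_rejected(self, rng):
        with pytest.raises(ValueError):
            awf_increment(np.array([0.5, 0.4]), 2, rng)

    def test_half_half_block_profiles(self, rng):
        # eta = (1/2, 1/2), n = 3: P(profile (2,1)) = 0.75, P((3,)) = 0.25
        eta = np.array([0.5, 0.5])
        draws = 10_000
        triple = sum(len(awf_increment(eta, 3, rng)) == 1 for _ in range(draws))
        se = math.sqrt(0.25 * 0.75 / draws)
        assert abs(triple / draws - 0.25) < 3 * se

    def test_increment_law_is_exchangeable(self, rng):
        # relabeling the sampled children leaves the law invariant
        model = DiscreteFrequency([([0.7, 0.2, 0.1], 1.0)])
        expected = awf_transition_matrix(model, 3, method="enumerate")
        draws = 10_000
        perm = {1: 2, 2: 3, 3: 1}
        counts = {}
        for _ in range(draws):
            pi = awf_increment(model.sample(rng), 3, rng)
            relabeled = Partition(3, [[perm[x] for x in b] for b in pi.blocks])
            counts[relabeled] = counts.get(relabeled, 0) + 1
        keys = list(expected.probs)
        chi2 = stats.chisquare(
            [counts.get(k, 0) for k in keys],
            [expected.probs[k] * draws for k in keys],
        )
        assert chi2.pvalue > 0.01


class TestTransitionMatrices:
    def test_awf_matches_brute_force_tables(self, oracle_fixtures):
        for name, fx in oracle_fixtures.items():
            if fx.kind != "frequency":
                continue
            for n, table in fx.tables.items():
                est = awf_transition_matrix(fx.model, n, method="enumerate")
                assert est.row_sum() == pytest.approx(1.0, abs=1e-12)
                for pi, p in table.items():
                    assert est.probs[pi] == pytest.approx(p, abs=1e-12), (name, n, pi)

    def test_ac_matches_brute_force_tables(self, oracle_fixtures):
        for name, fx in oracle_fixtures.items():
            if fx.kind != "offspring":
                continue
            for n, table in fx.tables.items():
                est = ac_transition_matrix(fx.model, n, method="enumerate")
                assert est.row_sum() == pytest.approx(1.0, abs=1e-12)
                for pi, p in table.items():
                    assert est.probs[pi] == pytest.approx(p, abs=1e-12), (name, n, pi)

    def test_half_half_labeled_probabilities(self):
        model = DeterministicFrequency([0.5, 0.5])
        est = awf_transition_matrix(model, 3, method="enumerate")
        pair = Partition(3, [[1, 2], [3]])
        triple = Partition(3, [[1, 2, 3]])
        assert est.probs[pair] == pytest.approx(0.25, abs=1e-14)
        assert est.probs[triple] == pytest.approx(0.25, abs=1e-14)

    def test_enumeration_requires_finite_model(self, rng):
        model = ac.PDPowerFrequency(ac.PDPowerParams(0.5, 0.0, 0.5, 10))
        with pytest.raises(ValueError):
            awf_transition_matrix(model, 2, method="enumerate")

    def test_monte_carlo_agrees_with_enumeration(self, rng):
        model = DiscreteFrequency(
            [([0.6, 0.3, 0.1], 0.5), ([1 / 3, 1 / 3, 1 / 3], 0.5)]
        )
        exact = awf_transition_matrix(model, 3, method="enumerate")
        mc = awf_transition_matrix(model, 3, method=("monte_carlo", 4000), rng=rng)
        for pi, p in exact.probs.items():
            assert abs(mc.probs[pi] - p) < max(4 * mc.se[pi], 1e-12)

    def test_pair_probability_equals_n2_merge_entry(self, oracle_fixtures):
        for fx in oracle_fixtures.values():
            matrix = (
                awf_transition_matrix(fx.model, 2, method="enumerate")
                if fx.kind == "frequency"
                else ac_transition_matrix(fx.model, 2, method="enumerate")
            )
            c, se = pair_coalescence_probability(fx.model)
            assert se == 0.0
            assert c == pytest.approx(matrix.probs[Partition(2, [[1, 2]])], abs=1e-12)

    def test_fixed_mass_partition_model_is_paintbox(self):
        # when eta (ordered) is a fixed mass partition for all N, the increment
        # law is the paint-box law from that mass partition
        from asymcoal.partitions import paintbox_partition_probability

        eta = [0.5, 0.3, 0.2]
        model = DeterministicFrequency(eta)
        est = awf_transition_matrix(model, 3, method="enumerate")
        rho = MassPartition(eta)
        for pi in all_partitions(3):
            assert est.probs[pi] == pytest.approx(
                paintbox_partition_probability(rho, pi), abs=1e-12
            )


class TestGenealogy:
    def test_one_hot_model_hits_mrca_in_one_generation(self):
        model = DeterministicFrequency([1.0, 0.0, 0.0, 0.0])
        trace = simulate_genealogy(model, 3, seed=7)
        assert trace.mrca_reached and trace.times[-1] == 1.0

    def test_replay_reproduces_partition_list(self):
        model = UniformFrequency(20)
        trace = simulate_genealogy(model, 5, seed=11)
        assert trace.replay() == trace.partitions
        counts = trace.block_counts()
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_wright_fisher_pair_mrca_time_geometric(self):
        # n = 2, uniform 1/N: T ~ Geometric(1/N), mean N
        N, reps = 50, 1000
        times = [
            simulate_genealogy(UniformFrequency(N), 2, seed=1000 + r).times[-1]
            for r in range(reps)
        ]
        mean = np.mean(times)
        se = np.std(times, ddof=1) / math.sqrt(reps)
        assert abs(mean - N) < 3 * se

    def test_seeded_traces_are_reproducible(self):
        model = UniformFrequency(30)
        t1 = simulate_genealogy(model, 4, seed=99, replicate=3)
        t2 = simulate_genealogy(model, 4, seed=99, replicate=3)
        assert t1.partitions == t2.partitions and t1.times == t2.times

    def test_rescaled_time_uses_c_N(self):
        model = DeterministicFrequency([1.0, 0.0])
        trace = simulate_genealogy(model, 2, seed=5, time_scale="rescaled")
        assert trace.times[-1] == pytest.approx(1.0)  # 1 generation x c_N = 1

    def test_bad_horizon_rejected(self):
        with pytest.raises(ValueError):
            simulate_genealogy(UniformFrequency(10), 2, 0, seed=1)

    def test_sample_larger_than_population_rejected(self):
        with pytest.raises(ValueError):
            simulate_genealogy(UniformFrequency(3), 4, seed=1)

    def test_jsonl_records_one_line_per_generation(self):
        trace = simulate_genealogy(UniformFrequency(10), 3, 5, seed=2)
        lines = trace.to_jsonl().strip().splitlines()
        assert len(lines) == len(trace.times)


class TestDiscrepancy:
    def test_identity_offspring_ac_is_identity_but_awf_is_not(self, rng):
        # xi = (1,...,1): without replacement the increment is always 0_n
        # (c~ = 0), while the induced with-replacement model eta = 1/N is the
        # classical Wright-Fisher (c = 1/N) -- the models differ at fixed N,
        # and the row-sum distance equals 2(1 - P_awf(0_3)) exactly.
        model = DiscreteOffspring([(np.ones(5, dtype=int), 1.0)])
        rep = ac.ac_awf_discrepancy(model, 3, 50, rng)
        assert rep.c_tilde_N == 0.0 and rep.c_N == pytest.approx(0.2)
        p0 = 5 * 4 * 3 / 5**3
        assert rep.norm == pytest.approx(2 * (1 - p0), abs=1e-12)

    def test_full_sweep_offspring_has_zero_discrepancy(self, rng):
        model = DiscreteOffspring([(np.array([2, 0]), 1.0)])
        rep = ac.ac_awf_discrepancy(model, 2, 50, rng)
        assert rep.norm == pytest.approx(0.0, abs=1e-14)
        assert rep.c_N == 1.0 and rep.c_tilde_N == 1.0

    def test_multinomial_discrepancy_small_and_positive(self, rng):
        model = ac.MultinomialOffspring(30)
        rep = ac.ac_awf_discrepancy(model, 3, 2000, rng)
        assert 0 < rep.norm < 10 * rep.mean_inv_sigma
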