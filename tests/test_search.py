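"""Partition enumeration, random sampling, Metropolis rule, SA and the
incremental outer loop."""

import math

import numpy as np
import pytest

import autolump as al
from conftest import random_partition_brute


class TestEnumeration:
    @pytest.mark.parametrize(
        "n,blocks,constrained",
        [(4, 2, ()), (5, 3, ()), (6, 3, (0,)), (6, 4, (0, 2)), (7, 2, (1,))],
    )
    def test_matches_brute_force_oracle(self, n, blocks, constrained):
        got = list(al.enumerate_constrained_partitions(n, blocks, constrained))
        expected = random_partition_brute(n, blocks, constrained)
        assert {p.block_of for p in got} == {p.block_of for p in expected}
        assert len(got) == len(expected)  # no duplicates
        assert len(got) == al.count_constrained_partitions(n, blocks, constrained)

    def test_three_free_states_into_two_blocks(self):
        assert len(list(al.enumerate_constrained_partitions(3, 2))) == 3

    def test_free_equals_blocks_yields_identity_only(self):
        got = list(al.enumerate_constrained_partitions(5, 5, (0,)))
        assert got == [al.LumpingPartition.identity(5, (0,))]

    def test_sixteen_free_states_into_two_blocks(self):
        """S(16, 2) = 2^15 - 1 = 32767 partitions of the 17-state problem."""
        assert al.count_constrained_partitions(17, 3, (0,)) == 32767
        count = sum(1 for _ in al.enumerate_constrained_partitions(17, 3, (0,)))
        assert count == 32767

    def test_infeasible_block_count_is_empty(self):
        assert list(al.enumerate_constrained_partitions(4, 5, ())) == []
        assert list(al.enumerate_constrained_partitions(4, 1, (0,))) == []

    def test_labeled_count_reporting(self):
        assert al.labeled_assignment_count(16, 16) == 16**16


class TestRandomSampling:
    def test_blocks_equal_free_count_gives_identity(self, rng):
        p = al.sample_random_partition(5, 5, (0,), rng)
        assert p.is_identity()

    def test_uniform_over_set_partitions(self):
        """Empirical frequencies over S(4,2)=7 partitions are uniform."""
        rng = np.random.default_rng(777)
        universe = {p.block_of for p in random_partition_brute(4, 2)}
        assert len(universe) == 7
        draws = 70_000
        counts = {b: 0 for b in universe}
        for _ in range(draws):
            counts[al.sample_random_partition(4, 2, (), rng).block_of] += 1
        expect = draws / 7
        se = math.sqrt(draws * (1 / 7) * (6 / 7))
        for c in counts.values():
            assert abs(c - expect) <= 3 * se

    def test_deterministic_under_seed(self):
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            seqs.append(
                tuple(al.sample_random_partition(8, 3, (0,), rng).block_of for _ in range(20))
            )
        assert seqs[0] == seqs[1]

    def test_infeasible_raises(self, rng):
        with pytest.raises(ValueError):
            al.sample_random_partition(4, 5, (), rng)


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert al.metropolis_accept(0.0, 1e-9, rng)
        assert al.metropolis_accept(-5.0, 1e-9, rng)

    def test_uphill_frozen_at_low_temperature(self, rng):
        assert not any(al.metropolis_accept(1.0, 1e-12, rng) for _ in range(1000))

    def test_nonpositive_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            al.metropolis_accept(1.0, 0.0, rng)

    def test_empirical_acceptance_rate(self):
        """P(accept | delta=1, T=1) = exp(-1) within 3 standard errors."""
        rng = np.random.default_rng(2024)
        trials = 100_000
        hits = sum(al.metropolis_accept(1.0, 1.0, rng) for _ in range(trials))
        p = math.exp(-1.0)
        se = math.sqrt(p * (1 - p) / trials)
        assert abs(hits / trials - p) <= 3 * se


class TestInnerAlgorithms:
    def test_nars_exhausts_small_space(self):
        """With samples >> space size NARS finds the enumeration minimum."""
        model = al.random_compartmental_system(6, seed=21)
        cfg = al.SearchConfig(method="nars", tolerance=1e-12, constrained_states={0})
        ev = al.PartitionEvaluator(model, al.CriterionConfig(tolerance=1e-12))
        best_enum, min_ard, _, _ = al.full_enumeration_at_m(ev, 3, cfg)
        rng = np.random.default_rng(9)
        _, best_nars = al.nars_at_m(ev, 3, 5000, cfg, rng)
        assert best_nars == pytest.approx(min_ard, rel=1e-12, abs=1e-15)

    def test_nars_single_sample_equals_that_partition(self):
        model = al.random_compartmental_system(6, seed=21)
        cfg = al.SearchConfig(method="nars", tolerance=1e-12, constrained_states={0}, seed=3)
        ev = al.PartitionEvaluator(model, al.CriterionConfig(tolerance=1e-12))
        part = al.sample_random_partition(6, 3, {0}, np.random.default_rng(3))
        got_part, got_ard = al.nars_at_m(ev, 3, 1, cfg, np.random.default_rng(3))
        assert got_part == part
        assert got_ard == ev.evaluate(part)

    def test_sa_temperature_trace_is_geometric(self):
        model = al.random_compartmental_system(6, seed=4)
        cfg = al.SearchConfig(method="sa", tolerance=1e-15, constrained_states={0})
        sa = al.SAConfig(initial_temperature=100.0, cooling_factor=0.95, max_iterations=50)
        ev = al.PartitionEvaluator(model, al.CriterionConfig(tolerance=1e-15))
        _, _, traces = al.sa_at_m(ev, 3, sa, cfg, np.random.default_rng(0))
        temps = np.array([t[1] for t in traces])
        its = np.array([t[0] for t in traces])
        assert np.allclose(temps, 100.0 * 0.95**its, rtol=1e-12)
        assert np.all(np.diff(temps) < 0)

    def test_sa_matches_enumeration_minimum(self):
        """Five seeded SA runs all reach the global minimum at fixed m."""
        model = al.random_compartmental_system(7, seed=13)
        cfg = al.SearchConfig(method="sa", tolerance=1e-15, constrained_states={0})
        ev = al.PartitionEvaluator(model, al.CriterionConfig(tolerance=1e-15))
        _, min_ard, _, _ = al.full_enumeration_at_m(ev, 3, cfg)
        sa = al.SAConfig()
        for seed in range(5):
            _, best, _ = al.sa_at_m(ev, 3, sa, cfg, np.random.default_rng(seed))
            assert best == pytest.approx(min_ard, abs=1e-9)


class TestIncrementalSearch:
    def test_huge_tolerance_accepts_fully_lumped(self):
        # seed chosen so the 2-state fully-lumped system has a finite AUC
        # (an unstable coarse lump would be rejected regardless of tolerance)
        model = al.random_compartmental_system(6, seed=3)
        res = al.incremental_search(
            model, al.SearchConfig(method="enumeration", tolerance=1e6, constrained_states={0})
        )
        assert res.m == 2 and res.accepted

    @pytest.mark.parametrize("method", ["enumeration", "nars", "sa", "scree-nars"])
    def test_recovers_true_block_structure(self, method, lumpable_32):
        model, truth = lumpable_32
        res = al.incremental_search(
            model,
            al.SearchConfig(
                method=method,
                tolerance=1e-6,
                constrained_states={0},
                nars_samples=20_000,
                seed=5,
            ),
        )
        assert res.m == truth.m
        assert res.accepted and res.ard_percent < 1e-6

    def test_tiny_tolerance_returns_identity(self):
        model = al.random_compartmental_system(4, seed=6)
        res = al.incremental_search(
            model,
            al.SearchConfig(method="enumeration", tolerance=1e-13, constrained_states={0}),
        )
        assert res.m == model.n
        assert res.final_partition.is_identity()
        assert res.accepted

    def test_reported_ard_reevaluates_identically(self, lumpable_412):
        """Internal consistency: the returned partition re-scores to the
        reported ARD%."""
        model, _ = lumpable_412
        res = al.incremental_search(
            model,
            al.SearchConfig(method="sa", tolerance=1e-6, constrained_states={0}, seed=8),
        )
        again = al.evaluate_partition(model, res.final_partition)
        assert again == pytest.approx(res.ard_percent, rel=1e-12, abs=1e-15)
        assert res.m == res.final_partition.m

    @pytest.mark.parametrize("method", ["nars", "sa"])
    def test_bit_reproducible_under_seed(self, method, lumpable_32):
        model, _ = lumpable_32
        cfg = al.SearchConfig(
            method=method, tolerance=1e-6, constrained_states={0}, nars_samples=5000, seed=31
        )
        r1 = al.incremental_search(model, cfg)
        r2 = al.incremental_search(model, cfg)
        assert r1.final_partition == r2.final_partition
        assert r1.ard_percent == r2.ard_percent
        assert r1.evaluations == r2.evaluations

    def test_constrained_state_stays_unlumped(self, lumpable_412):
        model, _ = lumpable_412
        res = al.incremental_search(
            model,
            al.SearchConfig(method="sa", tolerance=1e-6, constrained_states={0}, seed=1),
        )
        out_block = res.final_partition.block_of[0]
        assert res.final_partition.blocks[out_block] == [0]
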