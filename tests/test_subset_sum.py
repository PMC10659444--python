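import itertools

import numpy as np
import pytest

from residuehd import (
    SubsetSumInstance,
    build_factors,
    exact_dp,
    generate_instance,
    make_residue_base,
    solve,
)
from residuehd.subset_sum import smallest_feasible_m

FIG_ITEMS = (18, 4, 5, 10, 2, 23)


@pytest.fixture(scope="module")
def worked_instance():
    return SubsetSumInstance(FIG_ITEMS, 21)


class TestInstance:
    def test_moduli_cover_and_coprime(self, worked_instance):
        inst = worked_instance
        assert inst.moduli == [inst.m - 1, inst.m, inst.m + 1]
        assert inst.M > sum(inst.items)
        for a, b in itertools.combinations(inst.moduli, 2):
            assert np.gcd(a, b) == 1

    def test_smallest_feasible_m(self):
        # sum 62 needs (m-1)m(m+1) > 62: m=4 gives 60, m=6 gives 210
        assert smallest_feasible_m(62) == 6
        assert SubsetSumInstance(FIG_ITEMS, 21).m == 6

    def test_odd_m_rejected(self):
        with pytest.raises(ValueError):
            SubsetSumInstance((1, 2), 3, m=5)

    def test_insufficient_range_rejected(self):
        with pytest.raises(ValueError):
            SubsetSumInstance((100, 100, 100), 100, m=4)


class TestFactors:
    def test_two_entry_codebook_per_item(self, worked_instance):
        rb = make_residue_base(worked_instance.moduli, 128, seed=0)
        factors = build_factors(worked_instance, rb)
        assert len(factors) == len(FIG_ITEMS)
        assert sum(cb.size for cb in factors) == 2 * len(FIG_ITEMS)
        for cb, item in zip(factors, FIG_ITEMS):
            assert cb.labels == (0, item)

    def test_range_check(self, worked_instance):
        rb = make_residue_base([3, 5], 64, seed=0)  # M=15 < 62
        with pytest.raises(ValueError, match="larger m"):
            build_factors(worked_instance, rb)


class TestSolve:
    def test_worked_example_recovers_unique_subset(self, worked_instance):
        # exhaustive enumeration: {4,5,10,2} is the only subset summing
        # to 21, so a verified solution must select exactly it
        solutions = [
            mask
            for mask in itertools.product([False, True], repeat=6)
            if sum(s for s, b in zip(FIG_ITEMS, mask) if b) == 21
        ]
        assert solutions == [(False, True, True, True, True, False)]
        sol = solve(worked_instance, D=1024, seed=0)
        assert sol.converged
        assert sol.achieved_sum == 21
        assert tuple(sol.mask) == solutions[0]

    def test_zero_target_gives_empty_subset(self):
        inst = SubsetSumInstance(FIG_ITEMS, 0)
        sol = solve(inst, D=512, seed=1)
        assert sol.converged
        assert sol.achieved_sum == 0

    def test_full_sum_selects_everything(self):
        inst = SubsetSumInstance(FIG_ITEMS, sum(FIG_ITEMS))
        sol = solve(inst, D=512, seed=2)
        assert sol.converged
        assert sol.achieved_sum == sum(FIG_ITEMS)
        assert all(b for s, b in zip(FIG_ITEMS, sol.mask) if s > 0)

    def test_empty_items(self):
        sol = solve(SubsetSumInstance((), 0), D=64, seed=3)
        assert sol.converged and sol.mask == []

    def test_zero_item_is_degenerate(self):
        # a 0-valued item may land on either side of the mask without
        # breaking verification
        inst = SubsetSumInstance((0, 5, 7), 12)
        hits = sum(
            solve(inst, D=512, seed=s).converged for s in range(10)
        )
        assert hits == 10

    def test_soundness_no_false_success(self):
        # an infeasible target can never be reported as success
        inst = SubsetSumInstance((2, 4, 6), 5)
        sol = solve(inst, D=512, max_trials=3, seed=4)
        assert not sol.converged
        assert sol.achieved_sum != 5


class TestGenerator:
    def test_generated_instances_always_solvable(self):
        for s in range(20):
            inst = generate_instance(8, m=12, seed=s)
            dp = exact_dp(inst)
            assert dp is not None
            assert dp.achieved_sum == inst.target

    def test_subset_sum_moduli_product(self):
        inst = generate_instance(4, m=200, seed=0)
        assert inst.M == 199 * 200 * 201 == 7_999_800

    def test_empty_generation(self):
        inst = generate_instance(0, m=6, seed=1)
        assert inst.items == () and inst.target == 0


class TestExactDp:
    def test_worked_instance_solvable(self, worked_instance):
        dp = exact_dp(worked_instance)
        assert dp is not None and dp.achieved_sum == 21

    def test_parity_infeasible(self):
        assert exact_dp(SubsetSumInstance((2, 4, 6), 5)) is None

    def test_cross_validates_resonator(self):
        for s in range(10):
            inst = generate_instance(6, m=8, seed=100 + s)
            sol = solve(inst, D=512, seed=s)
            if sol.converged:
                assert sol.achieved_sum == inst.target
                assert exact_dp(inst) is not None


class TestLasVegas:
    def test_restart_success_compounds_independently(self):
        # single-trial success p-hat on one fixed instance; 3-trial
        # success must match 1-(1-p)^3 within binomial error
        inst = generate_instance(16, m=12, seed=7)
        D = 48
        n1, n3 = 250, 150
        ones = sum(
            solve(inst, D=D, max_trials=1, seed=s).converged for s in range(n1)
        )
        p1 = ones / n1
        assert 0.05 < p1 < 0.95, "instance should be neither trivial nor hopeless"
        threes = sum(
            solve(inst, D=D, max_trials=3, seed=10_000 + s).converged
            for s in range(n3)
        )
        p3 = threes / n3
        expected = 1 - (1 - p1) ** 3
        sd = np.sqrt(expected * (1 - expected) / n3 + p1 * (1 - p1) / n1)
        assert abs(p3 - expected) < 4 * sd

    def test_accuracy_improves_with_dimension(self):
        # same instance set, two vector dimensions
        hits = {D: 0 for D in (64, 512)}
        n = 40
        for s in range(n):
            inst = generate_instance(12, m=12, seed=500 + s)
            for D in hits:
                hits[D] += solve(inst, D=D, max_trials=1, seed=s).converged
        assert hits[512] >= hits[64]
        assert hits[512] > 0.6 * n
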