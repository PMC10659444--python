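"""Subset sum as vector factorization.

The target sum is encoded over moduli {m-1, m, m+1}; each item gets a
two-entry codebook (exclude = z(0), include = z(item)).  A resonator
fixed point selects a subset; every reported success is verified by
integer arithmetic, so only the number of restarts is random.
"""

from residuehd import SubsetSumInstance, exact_dp, generate_instance, solve

inst = SubsetSumInstance((18, 4, 5, 10, 2, 23), 21)
print(f"S={list(inst.items)}, T={inst.target}, moduli {inst.moduli} (M={inst.M})")
sol = solve(inst, D=1024, max_trials=10, seed=0)
print(f"resonator subset {sol.subset(inst)} sums to {sol.achieved_sum} "
      f"in {sol.trials_used} trial(s), {sol.evals} codebook evaluations")

dp = exact_dp(inst)
print(f"exact DP baseline agrees: subset {dp.subset(inst)} sums to {dp.achieved_sum}")

rand = generate_instance(12, m=12, seed=3)
rsol = solve(rand, D=512, seed=3)
print(f"\nrandom instance |S|={len(rand.items)}, T={rand.target}: "
      f"solved={rsol.converged} with sum {rsol.achieved_sum} "
      f"({rsol.trials_used} trial(s))")
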