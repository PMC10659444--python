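"""Subset-sum solving with a residue resonator network.

The subset-sum problem asks whether a multiset S of positive integers
contains a subset summing to a target T (NP-complete for positive
integers), and to return the subset.  The vector formulation encodes the
target as ``z(T)`` over a residue system with moduli ``{m-1, m, m+1}``
(pairwise co-prime when m is even) whose range M exceeds ``sum(S)``, and
gives the resonator one two-entry codebook per item: the identity
``z(0)`` ('exclude') and ``z(S_k)`` ('include').  A resonator fixed
point that multiplies out to ``z(T)`` is a subset selection.

Each run is a Las Vegas trial: the decoded mask is verified by ordinary
integer arithmetic, never trusted from the vectors, so a reported
success is always correct and only the number of restarts is random.
Restart success compounds as ``1 - (1 - p)^n`` across independent
random initializations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .residue_algebra import ResidueBase, make_residue_base
from .decoding import Codebook, resonator_run

__all__ = [
    "SubsetSumInstance",
    "SubsetSolution",
    "smallest_feasible_m",
    "build_factors",
    "solve",
    "generate_instance",
    "exact_dp",
]


def smallest_feasible_m(total: int) -> int:
    """Smallest even m with (m-1)*m*(m+1) > total.

    Even m keeps m-1 and m+1 co-prime (they differ by 2, so parity is
    the only shared-factor risk); m starts at 4 so every modulus is >= 2.
    """
    m = 4
    while (m - 1) * m * (m + 1) <= total:
        m += 2
    return m


@dataclass(frozen=True)
class SubsetSumInstance:
    """Items, target, and the residue system that will encode them."""

    items: tuple
    target: int
    m: Optional[int] = None

    def __post_init__(self) -> None:
        items = tuple(int(s) for s in self.items)
        object.__setattr__(self, "items", items)
        if any(s < 0 for s in items):
            raise ValueError("items must be nonnegative integers")
        if self.target < 0:
            raise ValueError("target must be nonnegative")
        m = self.m if self.m is not None else smallest_feasible_m(sum(items))
        if m % 2 != 0:
            raise ValueError("m must be even so that m-1 and m+1 are co-prime")
        if (m - 1) * m * (m + 1) <= sum(items):
            raise ValueError(
                f"effective range {(m-1)*m*(m+1)} does not exceed sum(S)="
                f"{sum(items)}; choose a larger m"
            )
        object.__setattr__(self, "m", int(m))

    @property
    def moduli(self) -> List[int]:
        return [self.m - 1, self.m, self.m + 1]

    @property
    def M(self) -> int:
        return (self.m - 1) * self.m * (self.m + 1)


@dataclass
class SubsetSolution:
    """An inclusion mask plus its integer-verified sum."""

    mask: List[bool]
    achieved_sum: int
    trials_used: int
    converged: bool
    evals: int = 0

    def subset(self, inst: SubsetSumInstance) -> List[int]:
        return [s for s, b in zip(inst.items, self.mask) if b]


def build_factors(inst: SubsetSumInstance, rb: ResidueBase) -> List[Codebook]:
    """One two-entry codebook per item: labels 0 (exclude) and S_k (include)."""
    if rb.M <= sum(inst.items):
        raise ValueError(
            f"residue range M={rb.M} must exceed sum(S)={sum(inst.items)}; "
            "rebuild with a larger m"
        )
    z0 = rb.encode(0)
    factors = []
    for s in inst.items:
        if s == 0:
            # include/exclude are the same vector for a zero item; a
            # single entry keeps the codebook well-formed
            factors.append(Codebook.from_vectors((0,), [z0]))
        else:
            factors.append(
                Codebook.from_vectors((0, int(s)), [z0, rb.encode(int(s))])
            )
    return factors


def solve(
    inst: SubsetSumInstance,
    D: int = 1024,
    max_trials: int = 10,
    seed: Union[int, None] = None,
    alpha: float = 0.95,
    max_iter: int = 200,
    rb: Optional[ResidueBase] = None,
) -> SubsetSolution:
    """Resonator subset-sum search with verified output and restarts.

    Encodes ``z(T)``, factorizes over the item codebooks from a fresh
    random initialization per trial, and accepts a decoded mask only if
    its integer sum equals the target.  Returns the first verified
    solution, or the last attempt flagged unconverged after
    ``max_trials`` restarts.  Items equal to 0 make include/exclude
    indistinguishable and either mask bit is accepted for them.
    """
    ss = np.random.SeedSequence(seed)
    if not inst.items:
        ok = inst.target == 0
        return SubsetSolution([], 0, 0, ok, 0)
    if rb is None:
        rb = make_residue_base(inst.moduli, D, seed=ss.spawn(1)[0])
    factors = build_factors(inst, rb)
    target_vec = rb.encode(inst.target)
    total_evals = 0
    last_mask: List[bool] = [False] * len(inst.items)
    for trial in range(1, max_trials + 1):
        state = resonator_run(
            target_vec,
            factors,
            alpha=alpha,
            max_iter=max_iter,
            init="random",
            seed=ss.spawn(1)[0],
        )
        total_evals += state.evals
        mask = [lab != 0 for lab in state.labels]
        achieved = sum(s for s, b in zip(inst.items, mask) if b)
        last_mask = mask
        if achieved == inst.target:
            return SubsetSolution(mask, achieved, trial, True, total_evals)
    achieved = sum(s for s, b in zip(inst.items, last_mask) if b)
    return SubsetSolution(last_mask, achieved, max_trials, False, total_evals)


def generate_instance(
    n_items: int,
    m: int = 200,
    seed: Union[int, None] = None,
) -> SubsetSumInstance:
    """Random feasible instance in the style of the scaling experiments.

    The maximum representable sum is capped at ``M/2``; items are drawn
    uniformly from ``[0, (M/2)/n_items]`` so any subset stays in range,
    and the target is the sum of a uniformly random subset (every subset
    equally likely), so the instance always has at least one solution.
    """
    if n_items < 0:
        raise ValueError("n_items must be nonnegative")
    if m % 2 != 0:
        raise ValueError("m must be even so that m-1 and m+1 are co-prime")
    M = (m - 1) * m * (m + 1)
    if n_items == 0:
        return SubsetSumInstance((), 0, m)
    hi = (M // 2) // n_items
    if hi < 1:
        raise ValueError(f"m={m} too small to draw {n_items} items")
    rng = np.random.default_rng(seed)
    items = tuple(int(v) for v in rng.integers(0, hi + 1, size=n_items))
    picks = rng.integers(0, 2, size=n_items).astype(bool)
    target = int(sum(s for s, b in zip(items, picks) if b))
    return SubsetSumInstance(items, target, m)


def exact_dp(inst: SubsetSumInstance) -> Optional[SubsetSolution]:
    """Exact dynamic-programming baseline; oracle for the stochastic solver.

    Standard reachable-sum table with parent pointers; returns None when
    no subset attains the target.  Memory is O(|S| * T).
    """
    n = len(inst.items)
    T = inst.target
    if T * max(n, 1) > 200_000_000:
        raise MemoryError("instance too large for the DP table budget")
    reachable = np.zeros((n + 1, T + 1), dtype=bool)
    reachable[0, 0] = True
    for i, s in enumerate(inst.items, start=1):
        reachable[i] = reachable[i - 1]
        if s <= T:
            reachable[i, s:] |= reachable[i - 1, : T + 1 - s]
    if not reachable[n, T]:
        return None
    mask = [False] * n
    t = T
    for i in range(n, 0, -1):
        s = inst.items[i - 1]
        if not reachable[i - 1, t]:
            mask[i - 1] = True
            t -= s
    return SubsetSolution(mask, T, 1, True, 0)
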