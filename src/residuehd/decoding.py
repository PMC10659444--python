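"""Codebook decoding, the resonator network, and capacity experiments.

Decoding asks: given ``z(x)``, recover ``x``.  Direct codebook decoding
stores all M candidate encodings and takes M inner products.  The
resonator network instead factorizes the composed vector into its
per-modulus parts, each drawn from a codebook of only ``m_k`` entries,
so the total budget is ``b = sum(m_k)`` vectors instead of
``M = prod(m_k)`` -- for {3, 5, 7} that is 15 instead of 105.

The resonator is a discrete-time dynamical system.  With codebook
matrices ``Z_j`` and current factor estimates ``zhat_i``, each update is

    zhat_j  <-  g( Z_j Z_j^H ( z  (*)  prod_{i != j} conj(zhat_i) ) )

where ``(*)`` is the Hadamard product and ``g`` projects every component
back to unit magnitude (zero components are replaced by 1).  Updates are
asynchronous round-robin: one factor per time step, every factor once
per sweep.  Convergence is declared when the cosine similarity between
successive concatenated states exceeds a threshold alpha (default 0.95),
after which each estimate is cleaned up to its nearest codebook entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import sympy

from .phasor_core import ModulusBase, PhasorVector, add_phase_noise
from .residue_algebra import ResidueBase, crt_reconstruct, make_residue_base

__all__ = [
    "Codebook",
    "ResonatorState",
    "CapacityResult",
    "codebook_decode",
    "resonator_run",
    "decode_residue_vector",
    "capacity_sweep",
    "consecutive_prime_moduli",
    "landau_max_range",
]


@dataclass(frozen=True)
class Codebook:
    """A labelled matrix of candidate vectors for one factor.

    ``matrix`` has one row per label; rows need not be unit-magnitude
    phasor vectors (object templates in the scene application are
    superpositions), but for residue decoding they are the ``m`` integer
    encodings of one modulus.
    """

    labels: tuple
    matrix: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=np.complex128)
        object.__setattr__(self, "matrix", mat)
        if len(self.labels) != mat.shape[0]:
            raise ValueError("one matrix row per label required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if mat.shape[0] < 1:
            raise ValueError("empty codebook")

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_modulus_base(cls, base: ModulusBase) -> "Codebook":
        """All m residue encodings of one modulus, labelled 0..m-1."""
        x = np.arange(base.m, dtype=np.int64)
        num = (base.indices[None, :] * x[:, None]) % base.m
        mat = np.exp((2j * np.pi / base.m) * num)
        return cls(tuple(range(base.m)), mat)

    @classmethod
    def from_residue_base(
        cls, rb: ResidueBase, labels: Optional[Sequence[int]] = None
    ) -> "Codebook":
        """Composed encodings of the given integers (default: all of [0, M))."""
        labs = tuple(range(rb.M)) if labels is None else tuple(int(v) for v in labels)
        mat = np.ones((len(labs), rb.dim), dtype=np.complex128)
        x = np.asarray(labs, dtype=np.int64)
        for base in rb.bases:
            num = (base.indices[None, :] * (x[:, None] % base.m)) % base.m
            mat *= np.exp((2j * np.pi / base.m) * num)
        return cls(labs, mat)

    @classmethod
    def from_vectors(cls, labels: Sequence, vectors: Sequence) -> "Codebook":
        rows = [
            v.values if isinstance(v, PhasorVector) else np.asarray(v)
            for v in vectors
        ]
        return cls(tuple(labels), np.vstack(rows))


def _as_values(z) -> np.ndarray:
    return z.values if isinstance(z, PhasorVector) else np.asarray(z, dtype=np.complex128)


def codebook_decode(z, cb: Codebook):
    """Label whose codebook row maximizes ``Re <z, conj(row)>``.

    Ties are broken in favor of the smallest label.
    """
    v = _as_values(z)
    if v.size != cb.dim:
        raise ValueError(f"dimension mismatch: {v.size} vs {cb.dim}")
    sims = np.real(cb.matrix.conj() @ v)
    best = sims.max()
    winners = [cb.labels[i] for i in np.flatnonzero(sims >= best - 1e-12)]
    return min(winners)


@dataclass
class ResonatorState:
    """Per-factor estimates plus bookkeeping from one resonator run."""

    estimates: List[np.ndarray]
    labels: List
    iterations: int
    converged: bool
    evals: int
    similarity: float = float("nan")


def _phase_normalize(v: np.ndarray) -> np.ndarray:
    """The resonator non-linearity g: keep phases, discard magnitudes.

    Components with exactly zero magnitude carry no phase and are
    replaced by 1.
    """
    mag = np.abs(v)
    out = np.where(mag == 0.0, 1.0 + 0j, v / np.where(mag == 0.0, 1.0, mag))
    return out


def _init_estimates(
    codebooks: Sequence[Codebook],
    init: str,
    rng: np.random.Generator,
) -> List[np.ndarray]:
    D = codebooks[0].dim
    ests = []
    for cb in codebooks:
        if init == "superposition":
            ests.append(_phase_normalize(cb.matrix.sum(axis=0)))
        elif init == "random":
            ests.append(np.exp(2j * np.pi * rng.random(D)))
        else:
            raise ValueError(f"unknown init {init!r}")
    return ests


def _commit_matrix(cb: Codebook) -> np.ndarray:
    """Codebook rows as the non-linearity g sees them (unit phasors).

    A factor estimate always passes through g, so at a fixed point it
    matches the *phase pattern* of its codebook entry; rows that are
    already unit-magnitude phasors are reused as-is.
    """
    norms = np.abs(cb.matrix)
    if np.allclose(norms, 1.0, atol=1e-9):
        return cb.matrix
    return _phase_normalize(cb.matrix)


def resonator_run(
    z,
    codebooks: Sequence[Codebook],
    alpha: float = 0.95,
    max_iter: int = 200,
    init: str = "superposition",
    seed: Union[int, np.random.SeedSequence, None] = None,
    commit_alpha: Optional[float] = None,
    require_commit: bool = True,
    initial_estimates: Optional[Sequence[np.ndarray]] = None,
) -> ResonatorState:
    """Factorize ``z`` into one codebook entry per factor.

    Convergence requires two conditions on the same sweep: the cosine
    similarity between successive concatenated states exceeds ``alpha``,
    and (unless ``require_commit`` is off) every factor estimate is
    *committed* -- its cleanup similarity with its nearest codebook entry
    exceeds ``commit_alpha`` (default: ``alpha``).  The second condition
    distinguishes a genuine fixed point from the slow early transient,
    whose successive states are also nearly parallel.  Callers decoding
    inputs that cannot be codebook entries (noisy or sub-integer
    encodings) lower ``commit_alpha`` or disable ``require_commit``.

    Returns a :class:`ResonatorState` whose ``labels`` are the cleaned-up
    (nearest-codebook, by inner-product magnitude) decisions for each
    factor.  ``evals`` counts every codebook row touched, including
    convergence checks and the final cleanup.  A run that hits
    ``max_iter`` without converging is flagged ``converged=False``; its
    labels are still the cleanup of the final state so that callers can
    score accuracy or restart.
    """
    if len(codebooks) < 1:
        raise ValueError("need at least one factor codebook")
    v = _as_values(z)
    dims = {cb.dim for cb in codebooks}
    if dims != {v.size}:
        raise ValueError("codebook dimensions must match the input vector")
    if commit_alpha is None:
        commit_alpha = alpha

    evals = 0
    if len(codebooks) == 1:
        # the update degenerates (the product over other factors is empty,
        # leaving z itself), so a single projection + cleanup is exactly
        # codebook decoding
        cb = codebooks[0]
        label = codebook_decode(v, cb)
        est = cb.matrix[cb.labels.index(label)].copy()
        return ResonatorState([est], [label], 1, True, cb.size, 1.0)

    rng = np.random.default_rng(seed)
    if initial_estimates is not None:
        ests = [np.asarray(e, dtype=np.complex128).copy() for e in initial_estimates]
    else:
        ests = _init_estimates(codebooks, init, rng)
    K = len(codebooks)
    D = v.size
    gmats = [_commit_matrix(cb) for cb in codebooks]

    # running Hadamard product of conj(estimates); estimates stay unit
    # magnitude so dividing by conj(est_j) is multiplying by est_j
    P = np.ones(D, dtype=np.complex128)
    for e in ests:
        P *= np.conj(e)

    converged = False
    sim = float("nan")
    it = 0
    cleanup_sims: List[Optional[np.ndarray]] = [None] * K
    for it in range(1, max_iter + 1):
        prev = [e.copy() for e in ests]
        for j, cb in enumerate(codebooks):
            target = v * P * ests[j]
            sims = cb.matrix.conj() @ target
            proj = sims @ cb.matrix
            new = _phase_normalize(proj)
            P *= np.conj(new) * ests[j]
            ests[j] = new
            evals += cb.size
        num = sum(float(np.real(np.vdot(p, e))) for p, e in zip(prev, ests))
        sim = num / (K * D)
        if sim >= alpha:
            if not require_commit:
                converged = True
                break
            committed = True
            for j, cb in enumerate(codebooks):
                # cleanup similarity: |<g(row), est>| / D; magnitude, not
                # real part, because the componentwise non-linearity
                # cannot remove a global phase e^{i*gamma}
                cs = np.abs(gmats[j] @ np.conj(ests[j])) / D
                cleanup_sims[j] = cs
                evals += cb.size
                if cs.max() < commit_alpha:
                    committed = False
            if committed:
                converged = True
                break

    labels = []
    for j, cb in enumerate(codebooks):
        if converged and cleanup_sims[j] is not None:
            cs = cleanup_sims[j]
        else:
            cs = np.abs(gmats[j] @ np.conj(ests[j]))
            evals += cb.size
        best = cs.max()
        winners = [cb.labels[i] for i in np.flatnonzero(cs >= best - 1e-12)]
        labels.append(min(winners))
    return ResonatorState(ests, labels, it, converged, evals, sim)


def decode_residue_vector(
    z,
    rb: ResidueBase,
    alpha: float = 0.95,
    max_iter: int = 200,
    init: str = "superposition",
    seed: Union[int, np.random.SeedSequence, None] = None,
) -> Tuple[int, ResonatorState]:
    """Resonator-factorize a composed residue encoding and CRT-reconstruct x."""
    codebooks = [Codebook.from_modulus_base(b) for b in rb.bases]
    state = resonator_run(z, codebooks, alpha=alpha, max_iter=max_iter, init=init, seed=seed)
    x = crt_reconstruct(state.labels, rb.moduli)
    return x, state


# -- capacity / noise experiments -------------------------------------------


@dataclass
class CapacityResult:
    """Accuracy table over ascending effective ranges at fixed D and K.

    ``capacity`` is the largest tested M whose empirical accuracy is at
    least ``accuracy_floor`` (the capacity definition C(D)).
    """

    D: int
    K: int
    kappa: Optional[float]
    table: pd.DataFrame
    capacity: int
    accuracy_floor: float = 0.95

    def to_csv(self, path: Union[str, Path]) -> None:
        out = self.table.copy()
        out.insert(0, "kappa", self.kappa if self.kappa is not None else np.inf)
        out.insert(0, "K", self.K)
        out.insert(0, "D", self.D)
        out.to_csv(path, index=False)


def consecutive_prime_moduli(K: int, min_M: int = 2) -> List[int]:
    """Smallest window of K consecutive primes whose product is >= min_M."""
    primes = [2]
    while True:
        if len(primes) >= K and math.prod(primes[-K:]) >= min_M:
            return primes[-K:]
        primes.append(int(sympy.nextprime(primes[-1])))


def _noise_commit_ceiling(kappa: Optional[float]) -> float:
    """Expected kernel attenuation under von Mises phase noise.

    E[cos eps] = I1(kappa)/I0(kappa); a noisy encoding can match its
    clean codebook entry at most this well on average, so the commit
    threshold is scaled down by it.
    """
    if kappa is None:
        return 1.0
    from scipy.special import i0e, i1e  # exponentially scaled: safe for large kappa

    return float(i1e(kappa) / i0e(kappa))


def evaluate_accuracy(
    rb: ResidueBase,
    trials: int,
    kappa: Optional[float] = None,
    alpha: float = 0.95,
    max_iter: int = 200,
    init: str = "superposition",
    seed: Union[int, np.random.SeedSequence, None] = None,
) -> Tuple[float, float, float]:
    """Monte-Carlo resonator accuracy on uniform random targets.

    All trials advance in lock-step so the per-sweep work is a handful
    of matrix-matrix products; each trial still follows the exact
    single-instance update rule and freezes as soon as it converges.
    Under phase noise the commit threshold is scaled by the Bessel-ratio
    attenuation of the expected kernel.  Returns
    ``(accuracy, mean_iterations, mean_evals)``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    codebooks = [Codebook.from_modulus_base(b) for b in rb.bases]
    commit_alpha = alpha * _noise_commit_ceiling(kappa)

    T = int(trials)
    D = rb.dim
    K = rb.K
    xs = rng.integers(0, rb.M, size=T)
    Z = np.ones((T, D), dtype=np.complex128)
    for base in rb.bases:
        num = (base.indices[None, :] * (xs[:, None] % base.m)) % base.m
        Z *= np.exp((2j * np.pi / base.m) * num)
    if kappa is not None:
        Z *= np.exp(1j * rng.vonmises(0.0, kappa, size=(T, D)))

    ests = []
    for cb in codebooks:
        if init == "superposition":
            row = _phase_normalize(cb.matrix.sum(axis=0))
            ests.append(np.tile(row, (T, 1)))
        elif init == "random":
            ests.append(np.exp(2j * np.pi * rng.random((T, D))))
        else:
            raise ValueError(f"unknown init {init!r}")
    P = np.ones((T, D), dtype=np.complex128)
    for e in ests:
        P *= np.conj(e)

    active = np.arange(T)
    labels = np.zeros((T, K), dtype=np.int64)
    iters = np.full(T, max_iter, dtype=np.int64)
    evals = np.zeros(T, dtype=np.int64)
    sweep_cost = sum(cb.size for cb in codebooks)

    for it in range(1, max_iter + 1):
        if len(active) == 0:
            break
        prev = [e[active].copy() for e in ests]
        commit_ok = np.ones(len(active), dtype=bool)
        cur_labels = np.zeros((len(active), K), dtype=np.int64)
        check_cost = 0
        for j, cb in enumerate(codebooks):
            target = Z[active] * P[active] * ests[j][active]
            sims = target @ cb.matrix.conj().T
            new = _phase_normalize(sims @ cb.matrix)
            P[active] *= np.conj(new) * ests[j][active]
            ests[j][active] = new
            cs = np.abs(new @ cb.matrix.conj().T) / D
            check_cost += cb.size
            cur_labels[:, j] = cs.argmax(axis=1)
            commit_ok &= cs.max(axis=1) >= commit_alpha
        evals[active] += sweep_cost + check_cost
        num = np.zeros(len(active))
        for p, e in zip(prev, ests):
            num += np.real(np.sum(np.conj(p) * e[active], axis=1))
        sim_ok = num / (K * D) >= alpha
        done = sim_ok & commit_ok
        if done.any():
            idx = active[done]
            labels[idx] = cur_labels[done]
            iters[idx] = it
            active = active[~done]
    if len(active):
        # unconverged trials keep the cleanup of their final state
        for j in range(K):
            cs = np.abs(ests[j][active] @ codebooks[j].matrix.conj().T)
            labels[active, j] = cs.argmax(axis=1)

    correct = 0
    for t in range(T):
        xhat = crt_reconstruct([int(l) for l in labels[t]], rb.moduli)
        correct += int(xhat == int(xs[t]))
    return correct / T, float(np.mean(iters)), float(np.mean(evals))


def capacity_sweep(
    D: int,
    K: int,
    kappa: Optional[float] = None,
    accuracy_floor: float = 0.95,
    trials: int = 25,
    seed: Union[int, None] = None,
    min_M: int = 2,
    max_sets: int = 50,
    alpha: float = 0.95,
    max_iter: int = 200,
) -> CapacityResult:
    """Sweep ascending consecutive-prime moduli sets until accuracy drops.

    For each window of K consecutive primes (starting at the smallest
    window with product >= ``min_M``) the resonator is scored on
    ``trials`` uniform random targets.  The sweep stops at the first M
    whose accuracy falls below ``accuracy_floor`` (or after ``max_sets``
    windows).  ``comparisons_per_decode`` normalizes mean inner-product
    evaluations by accuracy, the cost measure used to compare against
    direct codebook decoding.
    """
    ss = np.random.SeedSequence(seed)
    moduli = consecutive_prime_moduli(K, min_M)
    rows = []
    for i in range(max_sets):
        rb = make_residue_base(moduli, D, seed=ss.spawn(1)[0])
        acc, mean_it, mean_ev = evaluate_accuracy(
            rb, trials, kappa=kappa, alpha=alpha, max_iter=max_iter,
            seed=ss.spawn(1)[0],
        )
        rows.append(
            {
                "M": rb.M,
                "moduli": "x".join(str(m) for m in moduli),
                "accuracy": acc,
                "mean_iterations": mean_it,
                "mean_evals": mean_ev,
                "comparisons_per_decode": mean_ev / acc if acc > 0 else np.inf,
            }
        )
        if acc < accuracy_floor:
            break
        moduli = moduli[1:] + [int(sympy.nextprime(moduli[-1]))]
    table = pd.DataFrame(rows)
    ok = table[table["accuracy"] >= accuracy_floor]
    capacity = int(ok["M"].max()) if len(ok) else 0
    return CapacityResult(D, K, kappa, table, capacity, accuracy_floor)


# -- Landau budget argument --------------------------------------------------


@lru_cache(maxsize=None)
def _landau_table(b: int) -> tuple:
    # f[j] = max lcm of a partition of j, built prime by prime so each
    # prime contributes at most one part (a prime power)
    f = [1] * (b + 1)
    for p in sympy.primerange(2, b + 1):
        for j in range(b, p - 1, -1):
            pa = p
            while pa <= j:
                cand = f[j - pa] * pa
                if cand > f[j]:
                    f[j] = cand
                pa *= p
    return tuple(f)


def landau_max_range(b: int) -> int:
    """Largest effective range achievable with codebook budget b.

    This is Landau's function g(b): the maximum least common multiple of
    any partition of b, equivalently the largest product of pairwise
    co-prime parts summing to at most b.  It quantifies how far a fixed
    budget of ``sum(m_k) = b`` codebook vectors can reach:
    g(15) = 105 via the partition {3, 5, 7}.
    """
    if not isinstance(b, (int, np.integer)) or b < 1:
        raise ValueError(f"budget must be a positive integer, got {b!r}")
    if b > 200:
        raise ValueError("budget too large for the exhaustive search")
    return _landau_table(int(b))[b]
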