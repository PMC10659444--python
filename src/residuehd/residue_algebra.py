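"""Residue number encodings and the two binding operators.

A residue number system represents an integer by its remainders modulo a
set of pairwise co-prime moduli; the Chinese Remainder Theorem makes the
representation unique on ``[0, M)`` with ``M = prod(m_k)``.  Here each
per-modulus remainder lives in a random phasor vector, and the composite
code is the Hadamard (componentwise) product across moduli -- a fully
distributed residue number system.

Two binding operators act on encodings:

* ``bind_add`` -- the Hadamard product, which adds encoded values
  (phases add componentwise, carry-free).
* ``bind_mult`` -- multiplies encoded values.  Componentwise index
  multiplication of two encodings picks up an unwanted extra factor of
  the base index; an *anti-base* of componentwise modular inverses
  cancels it.  This requires prime moduli and bases sampled without
  index 0.

Both operators run on the exact integer-index path, so the homomorphisms
``bind_add(z(a), z(b)) == z(a+b mod M)`` and the multiplicative analogue
hold bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
import sympy

from .phasor_core import (
    ModulusBase,
    PhasorVector,
    make_modulus_base,
)

__all__ = [
    "ResidueBase",
    "AntiBase",
    "make_residue_base",
    "encode_residue",
    "residues_of",
    "crt_reconstruct",
    "bind_add",
    "additive_inverse",
    "make_anti_base",
    "bind_mult",
    "multiply_composed",
]

#: tolerance (radians) for snapping a foreign phasor angle to a root-of-unity grid
ANGLE_TOL = 1e-6


@dataclass(frozen=True)
class ResidueBase:
    """An ordered set of pairwise co-prime per-modulus bases sharing one D.

    ``M = prod(moduli)`` is the effective range of uniquely representable
    integers; ``b = sum(moduli)`` is the codebook budget a resonator
    needs to decode it (versus M vectors for direct codebook decoding).
    """

    bases: tuple
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("need at least one modulus")
        dims = {b.dim for b in self.bases}
        if len(dims) != 1:
            raise ValueError("all per-modulus bases must share one dimension")
        ms = [b.m for b in self.bases]
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                g = math.gcd(ms[i], ms[j])
                if g != 1:
                    raise ValueError(
                        f"moduli {ms[i]} and {ms[j]} share factor {g}; "
                        "moduli must be pairwise co-prime"
                    )

    @property
    def moduli(self) -> List[int]:
        return [b.m for b in self.bases]

    @property
    def M(self) -> int:
        return math.prod(self.moduli)

    @property
    def b(self) -> int:
        return sum(self.moduli)

    @property
    def dim(self) -> int:
        return self.bases[0].dim

    @property
    def K(self) -> int:
        return len(self.bases)

    def encode(self, x: int) -> PhasorVector:
        return encode_residue(self, x)

    def encode_factors(self, x: int) -> List[PhasorVector]:
        """Per-modulus encodings of x (the factors of the composed vector)."""
        return [b.encode(x) for b in self.bases]


def make_residue_base(
    moduli: Sequence[int],
    D: int,
    nonzero_only: bool = False,
    seed: Union[int, np.random.SeedSequence, None] = None,
) -> ResidueBase:
    """Independent random bases, one per modulus, spawned from one seed."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(len(moduli))
    bases = tuple(
        make_modulus_base(m, D, nonzero_only=nonzero_only, seed=child)
        for m, child in zip(moduli, children)
    )
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return ResidueBase(bases, seed_val)


def encode_residue(rb: ResidueBase, x: int) -> PhasorVector:
    """Hadamard product of per-modulus encodings; periodic in x with period M."""
    x = int(x) % rb.M
    M = rb.M
    num = np.zeros(rb.dim, dtype=np.int64)
    for base in rb.bases:
        num += (base.indices * (x % base.m)) % base.m * (M // base.m)
    return PhasorVector.from_phase_fraction(num % M, M)


def residues_of(x: int, moduli: Sequence[int]) -> List[int]:
    """Remainders of x for each modulus, e.g. 20 -> [2, 0, 6] for {3, 5, 7}."""
    return [int(x) % int(m) for m in moduli]


def crt_reconstruct(residues: Sequence[int], moduli: Sequence[int]) -> int:
    """Unique integer in [0, M) with the given remainders (CRT inverse)."""
    if len(residues) != len(moduli):
        raise ValueError("residues and moduli must have equal length")
    for r, m in zip(residues, moduli):
        if not 0 <= int(r) < int(m):
            raise ValueError(f"residue {r} out of range for modulus {m}")
    x, _ = sympy.ntheory.modular.crt([int(m) for m in moduli], [int(r) for r in residues])
    return int(x)


def bind_add(z1: PhasorVector, z2: PhasorVector) -> PhasorVector:
    """Componentwise product: adds encoded values (phases add).

    On the exact path the result's phases are exact rationals, so
    ``bind_add(z(x1), z(x2)).exact_equals(z(x1 + x2))`` holds bit-exactly.
    """
    if z1.dim != z2.dim:
        raise ValueError(f"dimension mismatch: {z1.dim} vs {z2.dim}")
    if z1.is_exact and z2.is_exact:
        d1, d2 = z1.phase_den, z2.phase_den
        lcm = d1 * d2 // math.gcd(d1, d2)
        if lcm > 2**62:
            raise OverflowError("phase denominator too large for exact path")
        num = z1.phase_num * (lcm // d1) + z2.phase_num * (lcm // d2)
        return PhasorVector.from_phase_fraction(num % lcm, lcm)
    return PhasorVector(z1.values * z2.values)


def additive_inverse(z: PhasorVector) -> PhasorVector:
    """Componentwise conjugate: ``bind_add(z, additive_inverse(z)) == z(0)``."""
    return z.conj()


@dataclass(frozen=True)
class AntiBase:
    """Componentwise modular multiplicative inverses of a prime-modulus base.

    If the parent base component is ``exp(2*pi*i*u/m)`` then the anti-base
    component is ``exp(2*pi*i*v/m)`` with ``u*v == 1 (mod m)``.
    """

    parent: ModulusBase
    inv_indices: np.ndarray

    def __post_init__(self) -> None:
        inv = np.asarray(self.inv_indices, dtype=np.int64)
        object.__setattr__(self, "inv_indices", inv)
        if not np.array_equal(
            (self.parent.indices * inv) % self.parent.m,
            np.ones(self.parent.dim, dtype=np.int64),
        ):
            raise ValueError("inv_indices are not componentwise inverses of the parent")

    @property
    def m(self) -> int:
        return self.parent.m


def make_anti_base(base: ModulusBase) -> AntiBase:
    """Anti-base of componentwise inverses; needs a prime m and no zero index."""
    if not sympy.isprime(base.m):
        raise ValueError(
            f"anti-base requires a prime modulus, got composite m={base.m}"
        )
    if (base.indices == 0).any():
        raise ValueError(
            "anti-base requires nonzero_only sampling: index 0 has no inverse"
        )
    inv = np.array([pow(int(u), -1, base.m) for u in base.indices], dtype=np.int64)
    return AntiBase(base, inv)


def _extract_index(z: PhasorVector, m: int) -> np.ndarray:
    """Recover integer phase indices of a root-of-unity phasor vector.

    Falls back to angle extraction for vectors without exact-phase
    metadata; an angle farther than ANGLE_TOL radians from every grid
    point signals a non-integer encoding and raises.
    """
    if z.is_exact:
        if m % z.phase_den != 0:
            raise ValueError(
                f"vector phases have denominator {z.phase_den}, "
                f"not a divisor of modulus {m}: not an integer encoding"
            )
        return (z.phase_num * (m // z.phase_den)) % m
    ang = np.angle(z.values) * m / (2.0 * np.pi)
    idx = np.rint(ang)
    err = np.abs(ang - idx) * 2.0 * np.pi / m
    if err.max() > ANGLE_TOL:
        raise ValueError(
            f"component angle is {err.max():.3g} rad from the nearest "
            f"2*pi/{m} grid point (tolerance {ANGLE_TOL}); "
            "input is not an integer encoding"
        )
    return idx.astype(np.int64) % m


def bind_mult(
    factors1: Sequence[PhasorVector],
    factors2: Sequence[PhasorVector],
    rb: ResidueBase,
    antibases: Sequence[AntiBase],
) -> PhasorVector:
    """Multiplicative binding on per-modulus factors.

    For each modulus the component indices r = u*x1 and s = u*x2 are
    combined as ``r*s*v mod m`` with v the anti-base inverse of u, giving
    index ``u*x1*x2``; the Hadamard product across moduli then equals
    ``encode_residue(rb, x1*x2 mod M)`` bit-exactly.
    """
    if not (len(factors1) == len(factors2) == rb.K == len(antibases)):
        raise ValueError("need one factor pair and one anti-base per modulus")
    M = rb.M
    num = np.zeros(rb.dim, dtype=np.int64)
    for z1, z2, base, anti in zip(factors1, factors2, rb.bases, antibases):
        if anti.parent is not base and not np.array_equal(
            anti.parent.indices, base.indices
        ):
            raise ValueError("anti-base does not match the residue base")
        r = _extract_index(z1, base.m)
        s = _extract_index(z2, base.m)
        idx = (r * s % base.m) * anti.inv_indices % base.m
        num += idx * (M // base.m)
    return PhasorVector.from_phase_fraction(num % M, M)


def multiply_composed(
    z1: PhasorVector,
    z2: PhasorVector,
    rb: ResidueBase,
    antibases: Sequence[AntiBase],
    seed: Union[int, None] = None,
) -> PhasorVector:
    """Multiply two *composed* residue encodings.

    The core operation needs per-modulus factors; when handed composed
    vectors this wrapper first recovers the factors with the resonator
    network, then applies :func:`bind_mult`.
    """
    from .decoding import Codebook, resonator_run  # deferred: avoids a cycle

    codebooks = [Codebook.from_modulus_base(b) for b in rb.bases]
    factors = []
    for z in (z1, z2):
        state = resonator_run(z, codebooks, seed=seed)
        factors.append(
            [b.encode(lab) for b, lab in zip(rb.bases, state.labels)]
        )
    return bind_mult(factors[0], factors[1], rb, antibases)
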