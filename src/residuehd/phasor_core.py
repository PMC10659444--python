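"""Random phasor bases and fractional power encoding modulo m.

The currency of the whole package is the *phasor vector*: a length-D
sequence of unit-magnitude complex numbers.  An integer x is encoded by
componentwise exponentiation of a random base vector, ``z(x) = z ** x``
(fractional power encoding, FPE).  When every base phase is an m-th root
of unity, congruent integers map to the *same* vector, which is what
lets a phasor vector represent a residue class modulo m.

Phases are stored as exact integer indices (``phi_j = 2*pi*k_j/m``) and
only materialized to complex numbers on demand.  All algebra on encoded
integers therefore happens on the integer-index path and is immune to
floating-point drift: two encodings of congruent values are bit-identical
arrays, not merely close.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "PhasorVector",
    "ModulusBase",
    "KernelEstimate",
    "make_modulus_base",
    "encode_mod",
    "kernel",
    "add_phase_noise",
    "save_base",
    "load_base",
    "indices_to_csv",
]

#: tolerance for the unit-magnitude invariant
UNIT_TOL = 1e-9
#: kernels within this of 1 are treated as exact similarity
KERNEL_ONE_TOL = 1e-6


def _materialize(num: np.ndarray, den: int) -> np.ndarray:
    """Complex phasors ``exp(2*pi*i*num/den)``.

    A single shared code path guarantees that equal exact phases always
    produce bit-identical floating point arrays.
    """
    return np.exp((2j * np.pi / den) * num)


@dataclass(frozen=True)
class PhasorVector:
    """A length-D vector of unit-magnitude complex components.

    Vectors built on the exact path additionally carry their phases as a
    common-denominator fraction of a full turn: component j has phase
    ``2*pi*phase_num[j]/phase_den``.  Vectors that have passed through a
    noise model or other non-exact operation carry only ``values``.
    """

    values: np.ndarray
    phase_num: Optional[np.ndarray] = field(default=None, repr=False)
    phase_den: Optional[int] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.complex128)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("PhasorVector requires a 1-D, non-empty array")
        dev = np.abs(np.abs(v) - 1.0)
        if dev.max() > UNIT_TOL:
            raise ValueError(
                f"components deviate from unit magnitude by {dev.max():.3g}"
            )

    @property
    def dim(self) -> int:
        return self.values.size

    @property
    def is_exact(self) -> bool:
        return self.phase_num is not None

    @classmethod
    def from_phase_fraction(cls, num: np.ndarray, den: int) -> "PhasorVector":
        """Build from exact phases ``2*pi*num/den``, canonicalized.

        Phases are reduced modulo one turn and the common denominator is
        reduced by the collective gcd, so any two equal phase patterns
        produce identical (num, den) pairs and hence bit-identical
        complex arrays.
        """
        den = int(den)
        if den < 1:
            raise ValueError("denominator must be a positive integer")
        num = np.asarray(num, dtype=np.int64) % den
        g = math.gcd(den, int(np.gcd.reduce(num))) if num.size else den
        if g > 1:
            num = num // g
            den = den // g
        return cls(_materialize(num, den), phase_num=num, phase_den=den)

    def exact_equals(self, other: "PhasorVector") -> bool:
        """Bit-exact equality on the integer/rational phase path."""
        if not (self.is_exact and other.is_exact):
            raise ValueError("exact_equals requires exact-phase vectors")
        return self.phase_den == other.phase_den and np.array_equal(
            self.phase_num, other.phase_num
        )

    def conj(self) -> "PhasorVector":
        if self.is_exact:
            return PhasorVector.from_phase_fraction(-self.phase_num, self.phase_den)
        return PhasorVector(np.conj(self.values))


@dataclass(frozen=True)
class KernelEstimate:
    """A similarity estimate ``(1/D) Re <z1, conj(z2)>`` in [-1, 1]."""

    value: float
    dimension: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.value <= 1.0 + 1e-9:
            raise ValueError(f"kernel value {self.value} outside [-1, 1]")

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class ModulusBase:
    """Random FPE base modulo m: integer phase indices k_j with phi_j = 2*pi*k_j/m.

    ``nonzero_only`` records that index 0 was excluded at sampling time;
    this is required before an anti-base (componentwise modular inverse)
    can exist, because 0 has no multiplicative inverse.
    """

    m: int
    indices: np.ndarray
    nonzero_only: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if self.m < 2:
            raise ValueError("modulus must be an integer >= 2")
        if idx.ndim != 1 or idx.size < 1:
            raise ValueError("indices must be a 1-D, non-empty integer array")
        if idx.min() < 0 or idx.max() >= self.m:
            raise ValueError("indices must lie in [0, m)")
        if self.nonzero_only and (idx == 0).any():
            raise ValueError("nonzero_only base contains a zero index")

    @property
    def dim(self) -> int:
        return self.indices.size

    def base_vector(self) -> PhasorVector:
        return self.encode(1)

    def encode(self, x: int) -> PhasorVector:
        return encode_mod(self, x)


def make_modulus_base(
    m: int,
    D: int,
    nonzero_only: bool = False,
    seed: Union[int, np.random.SeedSequence, None] = None,
) -> ModulusBase:
    """Sample a random base modulo ``m`` with ``D`` components.

    Indices are i.i.d. uniform on {0, ..., m-1}, or on {1, ..., m-1} when
    ``nonzero_only`` is set (a prerequisite for multiplicative binding).
    """
    if not isinstance(m, (int, np.integer)) or isinstance(m, bool) or m < 2:
        raise ValueError(f"modulus must be an integer >= 2, got {m!r}")
    if not isinstance(D, (int, np.integer)) or isinstance(D, bool) or D < 1:
        raise ValueError(f"dimension must be a positive integer, got {D!r}")
    rng = np.random.default_rng(seed)
    lo = 1 if nonzero_only else 0
    indices = rng.integers(lo, m, size=int(D), dtype=np.int64)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return ModulusBase(int(m), indices, bool(nonzero_only), seed_val)


def encode_mod(base: ModulusBase, x: int) -> PhasorVector:
    """FPE modulo m: component j is ``exp(2*pi*i * k_j * x / m)``.

    Arithmetic happens on integer indices, so congruent inputs yield
    bit-identical vectors: ``encode_mod(b, x) == encode_mod(b, x % m)``.
    """
    x = int(x)
    num = (base.indices * (x % base.m)) % base.m
    return PhasorVector.from_phase_fraction(num, base.m)


def kernel(z1: PhasorVector, z2: PhasorVector) -> KernelEstimate:
    """Normalized real inner product ``(1/D) Re <z1, conj(z2)>``."""
    if z1.dim != z2.dim:
        raise ValueError(f"dimension mismatch: {z1.dim} vs {z2.dim}")
    val = float(np.real(np.vdot(z2.values, z1.values)) / z1.dim)
    return KernelEstimate(min(1.0, max(-1.0, val)), z1.dim)


def add_phase_noise(
    z: PhasorVector,
    kappa: float,
    seed: Union[int, np.random.SeedSequence, None] = None,
) -> PhasorVector:
    """Multiply each component by ``exp(i*eps_j)``, eps_j ~ von Mises(0, kappa).

    Higher concentration kappa means less noise; the expected kernel
    between a vector and its noisy copy is the Bessel ratio I1(k)/I0(k).
    Unit magnitudes are preserved exactly; the result is no longer on
    the exact-phase path.
    """
    if not kappa > 0:
        raise ValueError(f"kappa must be > 0, got {kappa!r}")
    rng = np.random.default_rng(seed)
    eps = rng.vonmises(0.0, kappa, size=z.dim)
    return PhasorVector(z.values * np.exp(1j * eps))


# -- serialization -----------------------------------------------------------


def save_base(base: ModulusBase, path: Union[str, Path]) -> None:
    """Write a base to a portable ``.npz`` container with named fields."""
    np.savez(
        path,
        m=np.int64(base.m),
        indices=base.indices,
        D=np.int64(base.dim),
        nonzero_only=np.bool_(base.nonzero_only),
        seed=np.int64(-1 if base.seed is None else base.seed),
    )


def load_base(path: Union[str, Path]) -> ModulusBase:
    with np.load(path) as data:
        seed = int(data["seed"])
        return ModulusBase(
            int(data["m"]),
            data["indices"],
            bool(data["nonzero_only"]),
            None if seed < 0 else seed,
        )


def indices_to_csv(base: ModulusBase, path: Union[str, Path]) -> None:
    """Text export of the phase indices, one per line, for debugging."""
    np.savetxt(path, base.indices[None, :], fmt="%d", delimiter=",")
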