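"""Rational-number encoding and sub-integer resonator decoding.

Fractional power encoding extends from integers to rationals by direct
phase scaling: ``z(q)`` has component phases ``phi_j * q``.  The result
is no longer a residue number system (multiplicative binding is not
defined on rationals), but similarity and additive binding still work,
and -- remarkably -- rational encodings are near-fixed-points of the
resonator network even though its codebooks contain only integers.

Decoding to sub-integer precision proceeds in three steps:

1. run the resonator with integer codebooks to a fixed point;
2. clean up each factor to its nearest integer residue and reconstruct
   the nearest integer ``xhat`` by the CRT;
3. build ``r`` candidate encodings on the grid ``xhat + (i - r//2)/r``
   spanning a unit window around ``xhat``, and pick the best by
   codebook decoding.

The expected similarity profile at real offset ``delta`` is the product
over moduli of normalized Dirichlet kernels (a Dirac comb convolved
with a sinc-like kernel): exactly 1 at multiples of M, approximately 0
at every other integer, and oscillating in between.  The information
conveyed by one decoded vector is scored in bits from the decoding
accuracy ``a`` and the number of distinguishable states ``P``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import List, Optional, Sequence, Union

import numpy as np

from .phasor_core import ModulusBase, PhasorVector, kernel
from .residue_algebra import ResidueBase, crt_reconstruct
from .decoding import Codebook, ResonatorState, codebook_decode, resonator_run

__all__ = [
    "FractionalDecodeResult",
    "as_fraction",
    "encode_rational",
    "predicted_profile",
    "subinteger_decode",
    "bits_per_vector",
]


def as_fraction(q) -> Fraction:
    """Coerce to an exact rational.

    Floats are accepted through their shortest decimal representation
    (``40.4 -> 202/5``) rather than their binary expansion, since the
    caller invariably means the printed decimal.
    """
    if isinstance(q, Fraction):
        return q
    if isinstance(q, (int, np.integer)):
        return Fraction(int(q))
    if isinstance(q, float):
        return Fraction(repr(q))
    if isinstance(q, str):
        return Fraction(q)
    raise TypeError(f"cannot interpret {q!r} as an exact rational")


def encode_rational(base: Union[ModulusBase, ResidueBase], q) -> PhasorVector:
    """FPE of a rational: component phases are ``phi_j * q``, held exactly.

    Phases are accumulated as exact fractions of a turn before complex
    materialization, so ``z(q + m)`` equals ``z(q)`` bit-exactly and an
    integer q reproduces the integer encoder's output exactly.
    """
    q = as_fraction(q)
    p, s = q.numerator, q.denominator
    bases = base.bases if isinstance(base, ResidueBase) else (base,)
    M = math.prod(b.m for b in bases)
    den = M * s
    if den > 2**40:
        raise OverflowError("rational denominator too large for exact phases")
    num = np.zeros(bases[0].dim, dtype=np.int64)
    for b in bases:
        num += b.indices * ((p % (b.m * s)) * (den // (b.m * s)))
        num %= den
    return PhasorVector.from_phase_fraction(num, den)


def predicted_profile(moduli: Sequence[int], delta: float) -> float:
    """Expected kernel at real offset delta under uniform index sampling.

    The per-modulus expectation is the mean of ``exp(2*pi*i*k*delta/m)``
    over all m roots (a normalized Dirichlet kernel); moduli are
    independent, so the composite profile is the real part of the
    product.  Evaluates to 1 at ``delta == 0 (mod M)`` and to exactly 0
    at integers not divisible by any modulus structure.
    """
    val = 1.0 + 0j
    for m in moduli:
        k = np.arange(int(m))
        val *= np.exp(2j * np.pi * k * float(delta) / m).mean()
    return float(np.real(val))


@dataclass
class FractionalDecodeResult:
    """Outcome of three-step sub-integer decoding.

    ``value = crt_reconstruct(integer_part) + fractional_offset`` on the
    grid of r points per unit; ``confidence`` is the winning candidate's
    kernel with the input.
    """

    integer_part: List[int]
    fractional_offset: Fraction
    value: Fraction
    confidence: float
    converged: bool
    resonator: ResonatorState


def subinteger_decode(
    z,
    rb: ResidueBase,
    r: int = 10,
    alpha: float = 0.95,
    max_iter: int = 200,
    init: str = "superposition",
    seed: Union[int, None] = None,
) -> FractionalDecodeResult:
    """Decode a (possibly rational) encoding to 1/r resolution.

    With ``r == 1`` the candidate grid collapses to the integer itself
    and the procedure reduces to integer resonator decoding.  A run
    whose resonator does not converge is returned flagged rather than
    raised, so sweeps can score it as an error.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    codebooks = [Codebook.from_modulus_base(b) for b in rb.bases]
    # a rational encoding is not an integer codebook entry, so the
    # committed-fixed-point test cannot apply; convergence here means
    # only that the state has stopped moving
    state = resonator_run(
        z, codebooks, alpha=alpha, max_iter=max_iter, init=init, seed=seed,
        require_commit=False,
    )
    xhat = crt_reconstruct(state.labels, rb.moduli)
    offsets = [Fraction(i - r // 2, r) for i in range(r)]
    cands = [Fraction(xhat) + off for off in offsets]
    cand_cb = Codebook.from_vectors(
        range(len(cands)), [encode_rational(rb, c) for c in cands]
    )
    best = codebook_decode(z, cand_cb)
    zbest = PhasorVector(cand_cb.matrix[best])
    conf = float(kernel(PhasorVector(np.asarray(
        z.values if isinstance(z, PhasorVector) else z)), zbest))
    value = cands[best] % rb.M
    return FractionalDecodeResult(
        integer_part=list(state.labels),
        fractional_offset=offsets[best],
        value=value,
        confidence=conf,
        converged=state.converged,
        resonator=state,
    )


def bits_per_vector(a: float, P: int) -> float:
    """Information (bits) decoded per vector at accuracy a over P states.

        I(a, P) = a*log2(P*a) + (1 - a)*log2(P*(1 - a)/(P - 1))

    extended by continuity at a in {0, 1}.  The score is 0 at chance
    accuracy ``a = 1/P`` and reaches ``log2(P)`` at perfect accuracy,
    so it jointly credits being right and distinguishing many states.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {a!r}")
    if not isinstance(P, (int, np.integer)) or P < 2:
        raise ValueError(f"state count must be an integer >= 2, got {P!r}")
    first = a * math.log2(P * a) if a > 0.0 else 0.0
    second = (1.0 - a) * math.log2(P * (1.0 - a) / (P - 1)) if a < 1.0 else 0.0
    return first + second
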