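"""Multi-dimensional Cartesian encodings and hexagonal residue coordinates.

An n-dimensional integer point is encoded as the Hadamard product of
independent one-dimensional residue encodings, so vector addition in
``Z^n`` is again componentwise phase addition.

The hexagonal coordinate system mimics the grid-cell code of medial
entorhinal cortex.  A 2-D position ``x`` is projected onto three unit
axes at mutual angles of 120 degrees (the 'Mercedes-Benz' frame),
``y = Psi @ x``, and each of the three coordinates is phase-encoded
modulo m.  The per-component phase triples ``(k1, k2, k3)`` are sampled
under the zero-sum constraint ``k1 + k2 + k3 == 0 (mod m)``, which makes
``z([1, 1, 1]) == z([0, 0, 0])``: equal movement along all three axes
cancels, so every negative coordinate has a non-negative equivalent and
different paths to one 2-D position give one encoding.  The induced
similarity kernel has the six-fold symmetry characteristic of grid
cells, and a hexagonal code with modulus m resolves ``3m^2 - 3m + 1``
spatial states with ``3m`` codebook vectors, versus ``m^2`` states with
``2m`` vectors for a square lattice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .phasor_core import PhasorVector
from .residue_algebra import ResidueBase, bind_add

__all__ = [
    "HEX_FRAME",
    "MultiDimBase",
    "HexBase",
    "encode_nd",
    "hex_project",
    "make_hex_base",
    "encode_hex",
    "hex_state_count",
    "square_state_count",
    "codebook_cost",
    "enumerate_hex_states",
    "hex_entropy",
    "square_entropy",
]

# rows are unit vectors at mutual angles of 2*pi/3 (pairwise dot -1/2)
HEX_FRAME = np.array(
    [
        [-math.sqrt(3.0) / 2.0, -0.5],
        [math.sqrt(3.0) / 2.0, -0.5],
        [0.0, 1.0],
    ]
)


@dataclass(frozen=True)
class MultiDimBase:
    """One independent ResidueBase per spatial dimension, shared D."""

    bases: tuple

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise ValueError("need at least one dimension")
        if len({rb.dim for rb in self.bases}) != 1:
            raise ValueError("all dimensions must share one vector dimension D")

    @property
    def n(self) -> int:
        return len(self.bases)

    @property
    def dim(self) -> int:
        return self.bases[0].dim

    def encode(self, x: Sequence[int]) -> PhasorVector:
        return encode_nd(self, x)


def encode_nd(mdb: MultiDimBase, x: Sequence[int]) -> PhasorVector:
    """Hadamard product across dimensions: z(x) = z1(x1) (*) ... (*) zn(xn).

    Satisfies the translation law ``z(x) (*) z(x') == z(x + x')``
    bit-exactly on the integer-index path.
    """
    if len(x) != mdb.n:
        raise ValueError(f"point has {len(x)} components, base has {mdb.n}")
    out = mdb.bases[0].encode(int(x[0]))
    for rb, xi in zip(mdb.bases[1:], x[1:]):
        out = bind_add(out, rb.encode(int(xi)))
    return out


def hex_project(x: Sequence[float]) -> np.ndarray:
    """Project a 2-D point onto the three hexagonal axes: y = Psi @ x.

    The three rows of Psi sum to zero, so the components of y always sum
    to zero (y lies in the zero-sum plane).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (2,):
        raise ValueError("expected a 2-D point")
    return HEX_FRAME @ x


def hex_unproject(y: Sequence[float]) -> np.ndarray:
    """Least-squares inverse of the frame: maps a 3-D coordinate back to 2-D.

    Psi^T Psi = (3/2) I, so the pseudo-inverse is (2/3) Psi^T.
    """
    return (2.0 / 3.0) * (HEX_FRAME.T @ np.asarray(y, dtype=float))


@dataclass(frozen=True)
class HexBase:
    """Phase triples for the three hexagonal axes, zero-sum modulo m."""

    m: int
    k1: np.ndarray
    k2: np.ndarray
    k3: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for arr in (self.k1, self.k2, self.k3):
            if arr.shape != self.k1.shape or arr.ndim != 1:
                raise ValueError("triplet index arrays must share one 1-D shape")
        if ((self.k1 + self.k2 + self.k3) % self.m != 0).any():
            raise ValueError("phase triples must sum to 0 (mod m)")

    @property
    def dim(self) -> int:
        return self.k1.size

    def encode(self, p) -> PhasorVector:
        return encode_hex(self, p)


def make_hex_base(
    m: int,
    D: int,
    seed: Union[int, np.random.SeedSequence, None] = None,
) -> HexBase:
    """Sample D triples uniformly from {(k1,k2,k3): k1+k2+k3 == 0 (mod m)}.

    The constraint set is in bijection with (k1, k2) pairs, so sampling
    those uniformly and setting k3 = -(k1+k2) mod m is uniform on it.
    """
    if m < 2:
        raise ValueError("modulus must be >= 2")
    rng = np.random.default_rng(seed)
    k1 = rng.integers(0, m, size=D, dtype=np.int64)
    k2 = rng.integers(0, m, size=D, dtype=np.int64)
    k3 = (-(k1 + k2)) % m
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return HexBase(int(m), k1, k2, k3, seed_val)


def encode_hex(hb: HexBase, p) -> PhasorVector:
    """Encode a 3-D integer hex coordinate, or a continuous 2-D point.

    Integer coordinates use the exact index path, so
    ``encode_hex(y + [1,1,1]) == encode_hex(y)`` bit-exactly (the
    zero-sum constraint makes the all-ones translation invisible) and
    path independence holds.  A 2-D point is first projected with the
    frame and encoded with real-valued phases.
    """
    p = np.asarray(p)
    if p.shape == (2,):
        y = hex_project(p.astype(float))
        phase = (2.0 * np.pi / hb.m) * (hb.k1 * y[0] + hb.k2 * y[1] + hb.k3 * y[2])
        return PhasorVector(np.exp(1j * phase))
    if p.shape == (3,):
        a, b, c = (int(v) for v in p)
        num = (hb.k1 * (a % hb.m) + hb.k2 * (b % hb.m) + hb.k3 * (c % hb.m)) % hb.m
        return PhasorVector.from_phase_fraction(num, hb.m)
    raise ValueError("expected a 2-D point or a 3-D integer coordinate")


def hex_state_count(m: int) -> int:
    """Distinct states of a hexagonal code with modulus m: 3m^2 - 3m + 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 3 * m * m - 3 * m + 1


def square_state_count(m: int) -> int:
    """Distinct states of a square-lattice code with modulus m: m^2."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return m * m


def codebook_cost(m: int, lattice: str) -> int:
    """Codebook vectors needed to decode one period: 3m (hex) or 2m (square)."""
    if lattice == "hex":
        return 3 * m
    if lattice == "square":
        return 2 * m
    raise ValueError(f"unknown lattice {lattice!r}")


def enumerate_hex_states(m: int) -> List[Tuple[int, int, int]]:
    """All zero-sum integer triples within the hexagon of radius m - 1.

    These are the decodable coordinate states of one period of the
    hexagonal code; their count is the centered hexagonal number
    ``3m^2 - 3m + 1``, the closed form reported by
    :func:`hex_state_count`.
    """
    r = m - 1
    states = []
    for a in range(-r, r + 1):
        for b in range(-r, r + 1):
            c = -a - b
            if -r <= c <= r:
                states.append((a, b, c))
    return states


def _state_positions(states: Sequence[Tuple[int, int, int]]) -> np.ndarray:
    return np.array([hex_unproject(s) for s in states])


def hex_entropy(
    m: int,
    n_samples: int = 20000,
    seed: Union[int, None] = None,
) -> float:
    """Shannon entropy (bits) of the hexagonal state occupancy.

    2-D positions are sampled uniformly over one period of the code (the
    hexagon covered by the Voronoi cells of its states), assigned to the
    nearest decodable state (Voronoi assignment; ties go to the state
    listed first in canonical order), and the entropy of the induced
    state distribution is returned.  With enough samples this approaches
    ``log2(3m^2 - 3m + 1)`` up to boundary effects, which exceeds the
    square code's ``log2(m^2)`` at equal m.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    states = enumerate_hex_states(m)
    pos = _state_positions(states)
    rng = np.random.default_rng(seed)
    # sample within the hexagon {x : max |(Psi x)_i| <= m - 1/2} by rejection
    radius = (m - 0.5) * 2.0 / math.sqrt(3.0)  # circumscribing circle
    counts = np.zeros(len(states), dtype=np.int64)
    accepted = 0
    while accepted < n_samples:
        batch = max(1024, n_samples)
        pts = rng.uniform(-radius, radius, size=(batch, 2))
        y = pts @ HEX_FRAME.T
        keep = np.abs(y).max(axis=1) <= m - 0.5
        pts = pts[keep][: n_samples - accepted]
        if len(pts) == 0:
            continue
        d2 = ((pts[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        counts += np.bincount(d2.argmin(axis=1), minlength=len(states))
        accepted += len(pts)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def square_entropy(
    m: int,
    n_samples: int = 20000,
    seed: Union[int, None] = None,
) -> float:
    """Shannon entropy (bits) of the square-lattice state occupancy.

    Uniform samples over one m-by-m period are snapped to the nearest
    integer grid state; by symmetry the occupancy is uniform and the
    entropy approaches ``log2(m^2)``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-0.5, m - 0.5, size=(n_samples, 2))
    ix = np.rint(pts[:, 0]).astype(int) % m
    iy = np.rint(pts[:, 1]).astype(int) % m
    counts = np.bincount(ix * m + iy, minlength=m * m)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())
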