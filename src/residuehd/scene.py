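"""Visual-scene encoding and factorization into object identity and position.

The disentangling task: given a scene that contains one of a known set
of objects at an unknown 2-D translation, recover which object and
where.  A scene is first described as a set of sparse feature maps
``A_j(x, y)`` (in the original pipeline these come from convolutional
sparse coding of images; here a synthetic generator stands in, and any
externally computed feature maps can be supplied through the same
:class:`FeatureMap` container).  The maps are rolled up into one scene
vector by superposing position-bound feature identities:

    s = sum_{j,x,y}  h(x) (*) v(y) (*) d_j  *  A_j(x, y)

with ``h``/``v`` residue encodings of horizontal/vertical position and
``d_j`` a random phasor vector naming feature j.  Because encoding is
translation-equivariant, a template translated by ``(x', y')`` encodes
to ``h(x') (*) v(y') (*) O(i)``, so recognition reduces to factorizing
``s`` into position vectors and an object template -- a resonator
problem.

Two factorizations are supported: *standard* (3 factors: objects, all
horizontal positions, all vertical positions -- for 10 objects on a
105-wide grid that is 10 + 105*2 = 220 codebook vectors) and *residue*
(objects plus one factor per modulus per axis -- 10 + (3+5+7)*2 = 40
vectors for the same geometry), trading more factors for far fewer
stored vectors and fewer inner-product evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .phasor_core import PhasorVector
from .residue_algebra import ResidueBase, make_residue_base, crt_reconstruct
from .decoding import Codebook, resonator_run

__all__ = [
    "FeatureMap",
    "SceneVector",
    "ObjectTemplate",
    "SceneCodec",
    "generate_synthetic_scene",
    "encode_scene",
    "factorize_scene",
    "codebook_vector_count",
    "brute_force_search_size",
]


@dataclass(frozen=True)
class FeatureMap:
    """Sparse feature activations on a 2-D grid.

    Stored as parallel arrays (feature index, x, y, amplitude); the
    sparsity fraction is recorded for bookkeeping.  Reads and writes a
    plain CSV triplet table so externally computed sparse codes (e.g.
    from a learned convolutional dictionary) can be plugged in.
    """

    n_features: int
    width: int
    height: int
    feature: np.ndarray
    x: np.ndarray
    y: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.feature, dtype=np.int64)
        xs = np.asarray(self.x, dtype=np.int64)
        ys = np.asarray(self.y, dtype=np.int64)
        amp = np.asarray(self.amplitude, dtype=float)
        for name, arr in (("feature", f), ("x", xs), ("y", ys), ("amplitude", amp)):
            object.__setattr__(self, name, arr)
        if not (len(f) == len(xs) == len(ys) == len(amp)):
            raise ValueError("entry arrays must have equal length")
        if len(f) and (f.min() < 0 or f.max() >= self.n_features):
            raise ValueError("feature index out of range")
        if len(xs) and (xs.min() < 0 or xs.max() >= self.width):
            raise ValueError("x coordinate out of range")
        if len(ys) and (ys.min() < 0 or ys.max() >= self.height):
            raise ValueError("y coordinate out of range")
        if len(amp) and not np.isfinite(amp).all():
            raise ValueError("amplitudes must be finite")

    @property
    def n_entries(self) -> int:
        return len(self.feature)

    @property
    def sparsity(self) -> float:
        return self.n_entries / (self.n_features * self.width * self.height)

    def translated(self, dx: int, dy: int) -> "FeatureMap":
        """Toroidal shift: coordinates move by (dx, dy) modulo the grid."""
        return FeatureMap(
            self.n_features,
            self.width,
            self.height,
            self.feature,
            (self.x + dx) % self.width,
            (self.y + dy) % self.height,
            self.amplitude,
        )

    def scaled(self, c: float) -> "FeatureMap":
        return FeatureMap(
            self.n_features, self.width, self.height,
            self.feature, self.x, self.y, self.amplitude * c,
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {
                "feature": self.feature,
                "x": self.x,
                "y": self.y,
                "amplitude": self.amplitude,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: Union[str, Path], n_features: int, width: int, height: int
    ) -> "FeatureMap":
        df = pd.read_csv(path)
        return cls(
            n_features, width, height,
            df["feature"].to_numpy(), df["x"].to_numpy(),
            df["y"].to_numpy(), df["amplitude"].to_numpy(),
        )


@dataclass
class SceneVector:
    """A composed scene encoding; components need not be unit magnitude."""

    values: np.ndarray

    @property
    def dim(self) -> int:
        return self.values.size


@dataclass
class ObjectTemplate:
    """An object id, its canonical feature map, and its encoded vector O(i)."""

    object_id: int
    feature_map: FeatureMap
    vector: SceneVector


@dataclass
class SceneCodec:
    """Encoding bases shared by a family of scenes.

    ``h_base``/``v_base`` are residue bases over co-prime moduli whose
    product covers the grid side (e.g. {3, 5, 7} covers 105); ``d`` is a
    matrix of i.i.d. random phasor vectors naming the features.
    """

    h_base: ResidueBase
    v_base: ResidueBase
    d: np.ndarray

    @classmethod
    def make(
        cls,
        n_features: int,
        D: int,
        moduli: Sequence[int] = (3, 5, 7),
        seed: Union[int, np.random.SeedSequence, None] = None,
    ) -> "SceneCodec":
        ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
        s1, s2, s3 = ss.spawn(3)
        h = make_residue_base(list(moduli), D, seed=s1)
        v = make_residue_base(list(moduli), D, seed=s2)
        rng = np.random.default_rng(s3)
        d = np.exp(2j * np.pi * rng.random((n_features, D)))
        return cls(h, v, d)

    @property
    def dim(self) -> int:
        return self.h_base.dim

    @property
    def grid_range(self) -> int:
        return self.h_base.M


def encode_scene(fm: FeatureMap, codec: SceneCodec) -> SceneVector:
    """Superpose position-bound feature identities (linear in amplitudes)."""
    if fm.width > codec.h_base.M or fm.height > codec.v_base.M:
        raise ValueError(
            f"grid {fm.width}x{fm.height} exceeds residue range "
            f"{codec.h_base.M}x{codec.v_base.M}"
        )
    if fm.n_features > codec.d.shape[0]:
        raise ValueError("feature map uses more features than the codec names")
    s = np.zeros(codec.dim, dtype=np.complex128)
    for j, x, y, a in zip(fm.feature, fm.x, fm.y, fm.amplitude):
        s += (
            codec.h_base.encode(int(x)).values
            * codec.v_base.encode(int(y)).values
            * codec.d[int(j)]
            * float(a)
        )
    return SceneVector(s)


def generate_synthetic_scene(
    n_objects: int,
    grid: Tuple[int, int] = (105, 105),
    n_features: int = 16,
    entries_per_object: int = 12,
    seed: Union[int, None] = None,
) -> Tuple[List[FeatureMap], FeatureMap, Tuple[int, int, int]]:
    """Random sparse templates plus one translated scene.

    Stands in for a learned sparse-coding front end: each canonical
    template is a handful of feature activations at random grid sites
    with amplitudes uniform on [0.5, 1.5].  The scene is one template
    translated toroidally by a random ``(x', y')``, so translation
    equivariance of the encoding holds exactly.  Returns
    ``(templates, scene, (object_id, x', y'))``.
    """
    W, H = grid
    if entries_per_object < 1:
        raise ValueError("templates must have at least one active entry")
    rng = np.random.default_rng(seed)
    templates = []
    for _ in range(n_objects):
        sites = rng.choice(W * H, size=min(entries_per_object, W * H), replace=False)
        templates.append(
            FeatureMap(
                n_features, W, H,
                rng.integers(0, n_features, size=len(sites)),
                sites % W,
                sites // W,
                rng.uniform(0.5, 1.5, size=len(sites)),
            )
        )
    true_i = int(rng.integers(0, n_objects))
    dx = int(rng.integers(0, W))
    dy = int(rng.integers(0, H))
    scene = templates[true_i].translated(dx, dy)
    return templates, scene, (true_i, dx, dy)


def encode_templates(
    templates: Sequence[FeatureMap], codec: SceneCodec
) -> List[ObjectTemplate]:
    return [
        ObjectTemplate(i, fm, encode_scene(fm, codec))
        for i, fm in enumerate(templates)
    ]


def codebook_vector_count(
    n_objects: int, grid_side: int, moduli: Sequence[int], mode: str
) -> int:
    """Total stored codebook vectors for one factorization mode.

    standard: n_objects + 2 * grid_side; residue: n_objects +
    2 * sum(moduli).  For 10 objects, side 105, moduli {3,5,7}: 220 vs 40.
    """
    if mode == "standard":
        return n_objects + 2 * grid_side
    if mode == "residue":
        return n_objects + 2 * sum(int(m) for m in moduli)
    raise ValueError(f"unknown mode {mode!r}")


def brute_force_search_size(n_objects: int, grid_side: int) -> int:
    """Exhaustive joint search size: n_objects * side^2 (110,250 for 10x105^2)."""
    return n_objects * grid_side * grid_side


def _reconstruction_similarity(
    s: np.ndarray, codec: SceneCodec, obj_vec: np.ndarray, x: int, y: int
) -> float:
    recon = (
        codec.h_base.encode(x).values * codec.v_base.encode(y).values * obj_vec
    )
    denom = np.linalg.norm(s) * np.linalg.norm(recon)
    if denom == 0:
        return 0.0
    return float(np.abs(np.vdot(recon, s)) / denom)


def factorize_scene(
    s: Union[SceneVector, np.ndarray],
    templates: Sequence[ObjectTemplate],
    codec: SceneCodec,
    mode: str = "residue",
    alpha: float = 0.95,
    max_iter: int = 200,
    max_restarts: int = 5,
    match_threshold: float = 0.5,
    seed: Union[int, None] = None,
) -> Tuple[int, int, int, int, bool]:
    """Recover (object id, x', y') from a scene vector.

    ``mode='standard'`` uses 3 factors (objects, H, V with one entry per
    grid position); ``mode='residue'`` uses 1 + 2K factors (objects plus
    one factor per modulus per axis) and CRT-reconstructs the position.
    A converged run whose reconstruction similarity with the input falls
    below ``match_threshold`` is treated as a spurious fixed point and
    re-run from a fresh random initialization, up to ``max_restarts``.

    Returns ``(object_id, x, y, evals, ok)``.
    """
    sv = s.values if isinstance(s, SceneVector) else np.asarray(s)
    obj_cb = Codebook.from_vectors(
        [t.object_id for t in templates], [t.vector.values for t in templates]
    )
    side_x = codec.h_base.M
    side_y = codec.v_base.M
    if mode == "standard":
        codebooks = [
            obj_cb,
            Codebook.from_residue_base(codec.h_base, range(side_x)),
            Codebook.from_residue_base(codec.v_base, range(side_y)),
        ]
    elif mode == "residue":
        codebooks = [obj_cb]
        codebooks += [Codebook.from_modulus_base(b) for b in codec.h_base.bases]
        codebooks += [Codebook.from_modulus_base(b) for b in codec.v_base.bases]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ss = np.random.SeedSequence(seed)
    total_evals = 0
    best = (templates[0].object_id, 0, 0, False)
    for attempt in range(max_restarts + 1):
        init = "superposition" if attempt == 0 else "random"
        state = resonator_run(
            sv, codebooks, alpha=alpha, max_iter=max_iter, init=init,
            seed=ss.spawn(1)[0],
        )
        total_evals += state.evals
        if mode == "standard":
            obj_id, x, y = state.labels
        else:
            K = codec.h_base.K
            obj_id = state.labels[0]
            x = crt_reconstruct(state.labels[1 : 1 + K], codec.h_base.moduli)
            y = crt_reconstruct(state.labels[1 + K :], codec.v_base.moduli)
        obj_vec = obj_cb.matrix[list(obj_cb.labels).index(obj_id)]
        sim = _reconstruction_similarity(sv, codec, obj_vec, int(x), int(y))
        best = (int(obj_id), int(x), int(y), state.converged and sim >= match_threshold)
        if best[3]:
            break
    return best[0], best[1], best[2], total_evals, best[3]


def explain_away(
    s: Union[SceneVector, np.ndarray],
    templates: Sequence[ObjectTemplate],
    codec: SceneCodec,
    n_rounds: int,
    mode: str = "residue",
    seed: Union[int, None] = None,
    **kwargs,
) -> List[Tuple[int, int, int]]:
    """Sequentially decode a superposition of scenes by explaining away.

    Factorize, subtract the decoded object's reconstruction, repeat.
    Works for small superpositions of a few objects well within the
    resonator's capacity.
    """
    residual = np.array(s.values if isinstance(s, SceneVector) else s, dtype=complex)
    ss = np.random.SeedSequence(seed)
    found = []
    for _ in range(n_rounds):
        i, x, y, _, ok = factorize_scene(
            residual, templates, codec, mode=mode,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)), **kwargs,
        )
        found.append((i, x, y))
        obj_vec = templates[[t.object_id for t in templates].index(i)].vector.values
        residual = residual - (
            codec.h_base.encode(x).values * codec.v_base.encode(y).values * obj_vec
        )
    return found
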