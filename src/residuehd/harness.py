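"""Experiment configuration and deterministic fixtures.

Configs are plain-text ``key = value`` files so that runs are
reproducible and auditable without any binary tooling; every CLI run
logs its full effective config and master seed to standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Dict, List, Optional, Union

from .phasor_core import make_modulus_base
from .residue_algebra import make_residue_base
from .scene import SceneCodec, encode_templates, generate_synthetic_scene
from .subset_sum import SubsetSumInstance

__all__ = ["ExperimentConfig", "fixture_suite"]

_INT_FIELDS = {"seed", "D", "max_iter", "trials"}
_FLOAT_FIELDS = {"kappa", "alpha"}


@dataclass
class ExperimentConfig:
    """Validated experiment parameters; round-trips through text losslessly."""

    experiment: str
    seed: int = 0
    D: int = 1024
    moduli: List[int] = field(default_factory=lambda: [3, 5, 7])
    kappa: Optional[float] = None
    alpha: float = 0.95
    max_iter: int = 200
    trials: int = 100
    output: Optional[str] = None

    def __post_init__(self) -> None:
        if self.D < 1:
            raise ValueError("D must be a positive integer")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("kappa must be positive when given")
        if self.max_iter < 1 or self.trials < 1:
            raise ValueError("max_iter and trials must be positive")
        if not self.experiment:
            raise ValueError("experiment id must be non-empty")

    def to_text(self) -> str:
        lines = []
        for key, val in asdict(self).items():
            if val is None:
                continue
            if key == "moduli":
                val = ",".join(str(m) for m in val)
            lines.append(f"{key} = {val}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ExperimentConfig":
        fields: Dict[str, object] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            if key == "moduli":
                fields[key] = [int(v) for v in val.split(",") if v.strip()]
            elif key in _INT_FIELDS:
                fields[key] = int(val)
            elif key in _FLOAT_FIELDS:
                fields[key] = float(val)
            else:
                fields[key] = val
        return cls(**fields)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ExperimentConfig":
        return cls.from_text(Path(path).read_text())


def fixture_suite(seed: int = 0) -> Dict[str, object]:
    """Small deterministic fixtures used across the test suite.

    Same seed, same bytes: bases at D=256, the six-item worked subset-sum
    instance (S={18,4,5,10,2,23}, T=21), and a three-object synthetic
    scene on a 15x15 grid.
    """
    import numpy as np

    ss = np.random.SeedSequence(seed)
    s_mod, s_res, s_scene, s_codec = ss.spawn(4)
    base = make_modulus_base(5, 256, nonzero_only=True, seed=s_mod)
    rb = make_residue_base([3, 5, 7], 256, nonzero_only=True, seed=s_res)
    instance = SubsetSumInstance((18, 4, 5, 10, 2, 23), 21)
    codec = SceneCodec.make(n_features=8, D=256, moduli=(3, 5), seed=s_codec)
    templates, scene, truth = generate_synthetic_scene(
        3, grid=(15, 15), n_features=8, entries_per_object=6,
        seed=int(s_scene.generate_state(1)[0] % (2**31)),
    )
    return {
        "modulus_base": base,
        "residue_base": rb,
        "subset_sum_instance": instance,
        "scene_codec": codec,
        "scene_templates": templates,
        "scene": scene,
        "scene_truth": truth,
    }
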