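"""Scene configuration for the synthetic TIRF experiment generator."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["SceneConfig", "default_oligomer_distribution"]


def default_oligomer_distribution(k_max: int = 10, p: float = 0.5) -> np.ndarray:
    """Truncated geometric size distribution over oligomer sizes 1..k_max.

    Emulates a particle population dominated by monomers with a decaying tail
    of small oligomers up to ~10 molecules.
    """
    w = p ** np.arange(k_max, dtype=float)
    return w / w.sum()


@dataclass
class SceneConfig:
    """All parameters of a simulated single-molecule TIRF scene.

    Defaults describe the imaging regime this package targets: EMCCD TIRF
    imaging of GFP-tagged complexes diffusing on surface-immobilized
    microtubules at 1 frame per 113 ms.

    Attributes
    ----------
    image_size : (H, W) pixels.
    pixel_size : µm per px (100x objective on a 13 µm-pixel EMCCD).
    dt : seconds per frame.
    n_frames : frames per movie.
    psf_sigma : Gaussian PSF sigma, px.
    camera_gain : ADU per detected photon.
    read_noise_sd : Gaussian read noise, ADU.
    background_rate : background photons / px / frame.
    bleach_rate : 1/s per fluorophore.
    unit_intensity : photons / frame emitted per fluorophore.
    D : diffusion coefficient of mobile particles, µm²/s.
    static_fraction : probability a particle is statically bound.
    oligomer_size_distribution : probability vector over sizes 1..K.
    mt_intensity : photons / px / frame along the microtubule backbone
        (microtubule channel only).
    subframe_samples : 1 = position sampled once per frame (pair with
        motion-blur coefficient R = 0); >1 enables sub-frame averaging of the
        rendered position (pair with R = 1/6 in the diffusion estimator).
    seed : master seed; every stochastic draw flows from one generator.
    """

    image_size: tuple[int, int] = (64, 256)
    pixel_size: float = 0.13
    dt: float = 0.113
    n_frames: int = 200
    psf_sigma: float = 1.1
    camera_gain: float = 20.0
    read_noise_sd: float = 10.0
    background_rate: float = 20.0
    bleach_rate: float = 0.01
    unit_intensity: float = 300.0
    D: float = 0.05
    static_fraction: float = 0.2
    oligomer_size_distribution: np.ndarray = field(
        default_factory=default_oligomer_distribution
    )
    mt_intensity: float = 150.0
    subframe_samples: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.image_size = tuple(int(v) for v in self.image_size)
        self.oligomer_size_distribution = np.asarray(
            self.oligomer_size_distribution, dtype=float
        )
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if not 0 <= self.static_fraction <= 1:
            raise ValueError("static_fraction must lie in [0, 1]")
        p = self.oligomer_size_distribution
        if p.ndim != 1 or np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("oligomer_size_distribution must be a probability vector")
        if self.subframe_samples < 1:
            raise ValueError("subframe_samples must be >= 1")
        for name in ("psf_sigma", "camera_gain", "unit_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["oligomer_size_distribution"] = list(
            map(float, self.oligomer_size_distribution)
        )
        d["image_size"] = list(self.image_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scene config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SceneConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
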