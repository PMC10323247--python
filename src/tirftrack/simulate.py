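"""Ground-truth simulation: 1D diffusion on microtubule paths and photobleaching.

Particles bind a static, surface-immobilized microtubule and either stay put
(static subpopulation) or perform 1D Brownian motion along the filament with
reflecting boundaries at its ends.  No binding/unbinding kinetics: dwell times
span the whole movie, matching complexes that stay lattice-bound for the full
~2 min observation window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SceneConfig
from .containers import MicrotubulePath

__all__ = ["GroundTruth", "simulate_tracks", "simulate_photobleach_trace"]


def _reflect(s: np.ndarray, length: float) -> np.ndarray:
    """Fold positions into [0, length] by reflection at both ends."""
    if length <= 0:
        raise ValueError("path length must be positive")
    period = 2.0 * length
    s = np.mod(s, period)
    return np.where(s > length, period - s, s)


@dataclass
class GroundTruth:
    """True particle states for a rendered scene.

    Attributes
    ----------
    s : (n_particles, n_frames) arclength positions in µm (frame-time sample).
    s_sub : (n_particles, n_frames, S) sub-frame positions in µm when the
        scene is simulated with ``subframe_samples = S > 1``, else ``None``.
    oligomer_size : (n_particles,) true number of fluorophores.
    D : (n_particles,) true diffusion coefficient, µm²/s (0 for static).
    motility_class : (n_particles,) "static" or "diffusive".
    surviving : (n_particles, n_frames) surviving-fluorophore counts,
        non-increasing along time.
    path : the microtubule path the particles live on.
    """

    s: np.ndarray
    oligomer_size: np.ndarray
    D: np.ndarray
    motility_class: np.ndarray
    surviving: np.ndarray
    path: MicrotubulePath
    s_sub: np.ndarray | None = None

    @property
    def n_particles(self) -> int:
        return self.s.shape[0]

    @property
    def n_frames(self) -> int:
        return self.s.shape[1]

    def xy(self, frame: int) -> np.ndarray:
        """(n_particles, 2) pixel positions at a frame."""
        return self.path.point_at(self.s[:, frame])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per particle per frame."""
        n_p, n_f = self.s.shape
        pid = np.repeat(np.arange(n_p), n_f)
        frame = np.tile(np.arange(n_f), n_p)
        xy = self.path.point_at(self.s.ravel())
        return pd.DataFrame(
            {
                "particle_id": pid,
                "frame": frame,
                "arclength_um": self.s.ravel(),
                "x_px": xy[:, 0],
                "y_px": xy[:, 1],
                "oligomer_size": np.repeat(self.oligomer_size, n_f),
                "class": np.repeat(self.motility_class, n_f),
                "surviving_fluorophores": self.surviving.ravel(),
            }
        )


def simulate_tracks(
    config: SceneConfig,
    path: MicrotubulePath,
    n_particles: int = 10,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Simulate particle trajectories along a microtubule path.

    Diffusive particles follow ``s_{t+dt} = s_t + N(0, 2 D dt)`` in arclength
    with reflecting boundaries; static particles keep their initial position.
    The static/diffusive assignment is Bernoulli(``config.static_fraction``).
    Bitwise reproducible for a fixed ``rng`` / ``config.seed``.
    """
    if rng is None:
        rng = config.rng()
    L = path.length
    if L <= 0:
        raise ValueError("path length must be > 0")
    n_f = config.n_frames
    S = config.subframe_samples

    is_static = rng.random(n_particles) < config.static_fraction
    D = np.where(is_static, 0.0, config.D)
    sizes = 1 + rng.choice(
        len(config.oligomer_size_distribution),
        size=n_particles,
        p=config.oligomer_size_distribution,
    )

    s0 = rng.uniform(0.0, L, size=n_particles)
    step_sd = np.sqrt(2.0 * D * (config.dt / S))  # per sub-step
    steps = rng.normal(0.0, 1.0, size=(n_particles, n_f * S)) * step_sd[:, None]
    steps[:, 0] = 0.0  # first sample is the initial position
    s_sub = _reflect(s0[:, None] + np.cumsum(steps, axis=1), L)
    s_sub = s_sub.reshape(n_particles, n_f, S)
    s = s_sub[:, :, 0].copy()

    # per-fluorophore exponential bleach times -> surviving counts per frame
    kmax = int(sizes.max()) if n_particles else 0
    surviving = np.empty((n_particles, n_f), dtype=int)
    t = np.arange(n_f) * config.dt
    if config.bleach_rate > 0 and n_particles:
        bleach_t = rng.exponential(1.0 / config.bleach_rate, size=(n_particles, kmax))
        bleach_t[np.arange(kmax)[None, :] >= sizes[:, None]] = -1.0  # nonexistent
        surviving = (bleach_t[:, :, None] > t[None, None, :]).sum(axis=1)
    else:
        surviving[:] = sizes[:, None]

    return GroundTruth(
        s=s,
        oligomer_size=sizes,
        D=D,
        motility_class=np.where(is_static, "static", "diffusive"),
        surviving=surviving,
        path=path,
        s_sub=s_sub if S > 1 else None,
    )


def simulate_photobleach_trace(
    k: int,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
    n_frames: int | None = None,
) -> np.ndarray:
    """Integrated-intensity trace (ADU) of a k-fluorophore particle bleaching.

    Each fluorophore bleaches at an exponential time with rate
    ``config.bleach_rate``; the trace at frame t is
    ``surviving(t) * camera_gain * unit_intensity`` plus Gaussian noise of SD
    ``noise_sd`` (ADU).  After all fluorophores bleach, only noise remains.
    """
    if k < 1:
        raise ValueError("oligomer size k must be >= 1")
    if rng is None:
        rng = config.rng()
    n_f = config.n_frames if n_frames is None else n_frames
    t = np.arange(n_f) * config.dt
    if config.bleach_rate > 0:
        bleach_t = rng.exponential(1.0 / config.bleach_rate, size=k)
        surviving = (bleach_t[:, None] > t[None, :]).sum(axis=0)
    else:
        surviving = np.full(n_f, k)
    unit_adu = config.camera_gain * config.unit_intensity
    trace = surviving * unit_adu
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n_f)
    return trace.astype(float)
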