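"""Forward model: render ground-truth scenes into noisy EMCCD-like image stacks.

Each surviving fluorophore deposits an isotropic 2D Gaussian of total photon
count ``unit_intensity``; photon counts are Poisson, multiplied by the camera
gain, with additive Gaussian read noise.  The EMCCD excess-noise cascade is
approximated by this Poisson x gain + read-noise model, which is adequate for
testing estimators (documented in the methods note).  The microtubule channel
renders each filament as a static line with a Gaussian cross-section.
"""

from __future__ import annotations

import numpy as np

from .config import SceneConfig
from .containers import ImageStack, MicrotubulePath
from .simulate import GroundTruth

__all__ = ["render_stack", "render_microtubule_channel", "straight_path"]

_STAMP_HALF = 5  # Gaussian stamp half-width in units of psf_sigma


def straight_path(
    y: float, x0: float, x1: float, pixel_size: float = 0.13, n: int = 64
) -> MicrotubulePath:
    """A horizontal microtubule path along row ``y`` from ``x0`` to ``x1`` px."""
    xs = np.linspace(x0, x1, n)
    pts = np.stack([xs, np.full(n, float(y))], axis=1)
    return MicrotubulePath(pts, pixel_size=pixel_size)


def _deposit_gaussians(
    img: np.ndarray, xy: np.ndarray, photons: np.ndarray, sigma: float
) -> None:
    """Add Gaussian photon stamps (in place) for particles at ``xy`` px."""
    H, W = img.shape
    half = max(2, int(np.ceil(_STAMP_HALF * sigma)))
    for (x, y), n_ph in zip(xy, photons):
        if n_ph <= 0:
            continue
        cx, cy = int(round(x)), int(round(y))
        x_lo, x_hi = max(cx - half, 0), min(cx + half + 1, W)
        y_lo, y_hi = max(cy - half, 0), min(cy + half + 1, H)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        xs = np.arange(x_lo, x_hi) - x
        ys = np.arange(y_lo, y_hi) - y
        gx = np.exp(-0.5 * (xs / sigma) ** 2)
        gy = np.exp(-0.5 * (ys / sigma) ** 2)
        stamp = np.outer(gy, gx) * (n_ph / (2.0 * np.pi * sigma**2))
        img[y_lo:y_hi, x_lo:x_hi] += stamp


def _camera(
    expected_photons: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator | None,
    noise: bool,
    dtype: str,
) -> np.ndarray:
    """Photon expectation -> ADU frame (shot + read noise, gain, clipping)."""
    if noise:
        assert rng is not None
        counts = rng.poisson(expected_photons).astype(float)
        adu = counts * config.camera_gain
        if config.read_noise_sd > 0:
            adu = adu + rng.normal(0.0, config.read_noise_sd, size=adu.shape)
    else:
        adu = expected_photons * config.camera_gain
    if dtype == "uint16":
        return np.clip(np.round(adu), 0, 65535).astype(np.uint16)
    return adu.astype(np.float32)


def render_stack(
    truth: GroundTruth,
    config: SceneConfig,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    dtype: str = "float32",
) -> ImageStack:
    """Render the complex (GFP) channel of a simulated scene.

    With ``noise=False`` the expected photon image (times gain) is returned;
    useful as an oracle for PSF normalization and fitting bias.  ``dtype``
    may be ``"float32"`` or ``"uint16"`` (clipped at the 16-bit range).
    """
    if truth.n_frames > config.n_frames:
        raise ValueError("ground truth has more frames than the scene config")
    if rng is None and noise:
        rng = config.rng()
    H, W = config.image_size
    frames = np.empty((truth.n_frames, H, W), dtype=np.uint16 if dtype == "uint16" else np.float32)
    S = config.subframe_samples
    for f in range(truth.n_frames):
        expected = np.full((H, W), float(config.background_rate))
        alive = truth.surviving[:, f] > 0
        if np.any(alive):
            if truth.s_sub is not None and S > 1:
                # particle moves during exposure: deposit 1/S of the photons
                # at each sub-frame position (motion blur; pair with R = 1/6)
                for j in range(S):
                    xy = truth.path.point_at(truth.s_sub[alive, f, j])
                    photons = truth.surviving[alive, f] * config.unit_intensity / S
                    _deposit_gaussians(expected, xy, photons, config.psf_sigma)
            else:
                xy = truth.path.point_at(truth.s[alive, f])
                photons = truth.surviving[alive, f] * config.unit_intensity
                _deposit_gaussians(expected, xy, photons, config.psf_sigma)
        frames[f] = _camera(expected, config, rng, noise, dtype)
    return ImageStack(frames, channel="complex", pixel_size=config.pixel_size, dt=config.dt)


def render_microtubule_channel(
    paths: list[MicrotubulePath] | MicrotubulePath,
    config: SceneConfig,
    n_frames: int | None = None,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    dtype: str = "float32",
) -> ImageStack:
    """Render static microtubules as lines with a Gaussian cross-section.

    The filament backbone is sampled at sub-pixel steps and each sample
    deposits a small Gaussian, giving a smooth line of peak surface brightness
    ~``config.mt_intensity`` photons/px/frame on top of the background.
    """
    if isinstance(paths, MicrotubulePath):
        paths = [paths]
    if rng is None and noise:
        rng = config.rng()
    n_f = config.n_frames if n_frames is None else n_frames
    H, W = config.image_size
    sigma = config.psf_sigma
    expected = np.full((H, W), float(config.background_rate))
    for path in paths:
        step_um = 0.25 * config.pixel_size
        s = np.arange(0.0, path.length + step_um, step_um)
        xy = path.point_at(s)
        # photons per sample chosen so the ridge peak ~ mt_intensity:
        # line of Gaussians spaced ds has peak density 1/(sqrt(2 pi) sigma ds)
        per_sample = config.mt_intensity * np.sqrt(2 * np.pi) * sigma * 0.25
        _deposit_gaussians(expected, xy, np.full(len(s), per_sample), sigma)
    frames = np.empty((n_f, H, W), dtype=np.uint16 if dtype == "uint16" else np.float32)
    for f in range(n_f):
        frames[f] = _camera(expected, config, rng, noise, dtype)
    return ImageStack(frames, channel="microtubule", pixel_size=config.pixel_size, dt=config.dt)
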