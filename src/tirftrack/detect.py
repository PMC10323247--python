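"""Sub-pixel spot detection by local-maximum candidates + 2D Gaussian fits.

Detection follows the classic single-molecule recipe: robust (MAD-based)
noise estimation, matched-filter smoothing for candidate maxima, then an
unweighted least-squares fit of an isotropic 2D Gaussian with constant local
background in a small window around each candidate.  Fits that fail to
converge, leave the sigma bounds, or fall below the SNR acceptance threshold
are discarded.  The integrated intensity is the fitted Gaussian volume
``2 pi A sigma^2`` (background-subtracted, ADU).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .config import SceneConfig
from .containers import ImageStack, Spot

__all__ = ["detect_spots", "detect_stack", "robust_background", "unit_intensity_for_snr"]


def robust_background(frame: np.ndarray) -> tuple[float, float]:
    """Median background level and MAD-based noise SD of a frame (ADU)."""
    med = float(np.median(frame))
    mad = float(np.median(np.abs(frame - med)))
    return med, 1.4826 * mad


def unit_intensity_for_snr(config: SceneConfig, snr: float) -> float:
    """Photons/frame per fluorophore giving a desired peak SNR.

    SNR is defined as the peak amplitude of a monomer PSF above background,
    divided by the robust per-pixel noise SD of the background (shot noise of
    the background plus read noise, in ADU).
    """
    noise_adu = np.hypot(
        config.camera_gain * np.sqrt(config.background_rate), config.read_noise_sd
    )
    amp_adu = snr * noise_adu
    return float(amp_adu * 2.0 * np.pi * config.psf_sigma**2 / config.camera_gain)


def _gauss_model(p: np.ndarray, xg: np.ndarray, yg: np.ndarray) -> np.ndarray:
    amp, x0, y0, sigma, offset = p
    return offset + amp * np.exp(-((xg - x0) ** 2 + (yg - y0) ** 2) / (2.0 * sigma**2))


def _fit_spot(
    frame: np.ndarray,
    cx: int,
    cy: int,
    psf_sigma_guess: float,
    window: int,
    bg: float,
) -> tuple[np.ndarray, float, bool, float] | None:
    """Least-squares Gaussian fit in a window; returns (params, rms, ok, x_sd)."""
    H, W = frame.shape
    half = window // 2
    x_lo, x_hi = max(cx - half, 0), min(cx + half + 1, W)
    y_lo, y_hi = max(cy - half, 0), min(cy + half + 1, H)
    if (x_hi - x_lo) < 5 or (y_hi - y_lo) < 5:
        return None
    sub = frame[y_lo:y_hi, x_lo:x_hi].astype(float)
    yg, xg = np.mgrid[y_lo:y_hi, x_lo:x_hi].astype(float)

    amp0 = max(float(frame[cy, cx]) - bg, 1e-3)
    p0 = np.array([amp0, float(cx), float(cy), psf_sigma_guess, bg])
    lo = [0.0, x_lo - 0.5, y_lo - 0.5, 0.5 * psf_sigma_guess, -np.inf]
    hi = [np.inf, x_hi - 0.5, y_hi - 0.5, 3.0 * psf_sigma_guess, np.inf]

    def resid(p: np.ndarray) -> np.ndarray:
        return (_gauss_model(p, xg, yg) - sub).ravel()

    try:
        res = least_squares(resid, p0, bounds=(lo, hi), max_nfev=200)
    except Exception:
        return None
    if not res.success and res.status <= 0:
        return None
    dof = max(sub.size - 5, 1)
    rms = float(np.sqrt(np.sum(res.fun**2) / dof))
    # positional uncertainty from the Jacobian (Gauss-Newton covariance)
    x_sd = np.nan
    try:
        JTJ = res.jac.T @ res.jac
        cov = np.linalg.pinv(JTJ) * rms**2
        x_sd = float(np.sqrt(max(cov[1, 1], 0.0)))
    except Exception:
        pass
    return res.x, rms, True, x_sd


def _refit_two_emitters(
    frame: np.ndarray,
    spot_x: float,
    spot_y: float,
    sigma: float,
    bg: float,
    window: int,
) -> tuple[np.ndarray, float] | None:
    """Fit two fixed-width Gaussians around a suspiciously broad single fit.

    Returns ``((a1, x1, y1, a2, x2, y2, offset), rss)`` or None.  Used to
    resolve partially overlapping particles whose superposed image fits a
    single Gaussian only with inflated sigma.
    """
    H, W = frame.shape
    half = window // 2 + 2
    cx, cy = int(round(spot_x)), int(round(spot_y))
    x_lo, x_hi = max(cx - half, 0), min(cx + half + 1, W)
    y_lo, y_hi = max(cy - half, 0), min(cy + half + 1, H)
    if (x_hi - x_lo) < 7 or (y_hi - y_lo) < 7:
        return None
    sub = frame[y_lo:y_hi, x_lo:x_hi].astype(float)
    yg, xg = np.mgrid[y_lo:y_hi, x_lo:x_hi].astype(float)
    s2 = 2.0 * sigma**2

    def model(p: np.ndarray) -> np.ndarray:
        a1, x1, y1, a2, x2, y2, off = p
        return (
            off
            + a1 * np.exp(-((xg - x1) ** 2 + (yg - y1) ** 2) / s2)
            + a2 * np.exp(-((xg - x2) ** 2 + (yg - y2) ** 2) / s2)
        )

    amp0 = max(float(frame[cy, cx]) - bg, 1e-3)
    p0 = np.array([amp0, spot_x - 0.8, spot_y, amp0, spot_x + 0.8, spot_y, bg])
    lo = [0, x_lo - 0.5, y_lo - 0.5, 0, x_lo - 0.5, y_lo - 0.5, -np.inf]
    hi = [np.inf, x_hi - 0.5, y_hi - 0.5, np.inf, x_hi - 0.5, y_hi - 0.5, np.inf]
    try:
        res = least_squares(
            lambda p: (model(p) - sub).ravel(), p0, bounds=(lo, hi), max_nfev=200
        )
    except Exception:
        return None
    if not res.success and res.status <= 0:
        return None
    return res.x, float(np.sum(res.fun**2))


def _try_split(
    frame: np.ndarray,
    x0: float,
    y0: float,
    psf_sigma: float,
    bg: float,
    window: int,
    amp_min: float,
    W: int,
    H: int,
) -> list[Spot] | None:
    """Accept a two-emitter refit only if it clearly beats the single fit."""
    two = _refit_two_emitters(frame, x0, y0, psf_sigma, bg, window)
    if two is None:
        return None
    (a1, x1, y1, a2, x2, y2, off), rss2 = two
    # single-Gaussian RSS over the same window, free sigma
    single = _fit_spot(frame, int(round(x0)), int(round(y0)), psf_sigma, window + 4, bg)
    if single is None:
        return None
    p1, rms1, _, _ = single
    n_pix = (window + 4 - (window + 4) % 2 + 1) ** 2  # odd window side squared
    rss1 = rms1**2 * max(n_pix - 5, 1)
    sep = np.hypot(x1 - x2, y1 - y2)
    if rss2 >= 0.85 * rss1 or sep <= 1.2:
        return None
    if min(a1, a2) < amp_min:
        return None
    out = []
    for a, x, y in ((a1, x1, y1), (a2, x2, y2)):
        if not (0 <= x < W and 0 <= y < H):
            return None
        out.append(
            Spot(
                frame=0, x=float(x), y=float(y), sigma=float(psf_sigma),
                integrated_intensity=float(2.0 * np.pi * a * psf_sigma**2),
                local_background=float(off), fit_uncertainty=np.nan,
            )
        )
    return out


def detect_spots(
    frame: np.ndarray,
    psf_sigma_guess: float = 1.1,
    snr_min: float = 4.0,
    window: int = 9,
    min_separation: float | None = None,
    two_emitter: bool = True,
) -> list[Spot]:
    """Detect sub-pixel spots in a single frame.

    Candidates are local maxima of the matched-filtered image whose raw value
    exceeds ``background + snr_min * noise_sd`` (robust MAD noise).  Each
    candidate is refined by a 2D Gaussian fit; the fit must converge, keep
    sigma within [0.5, 3] x guess (strict, as a shape filter), and have a
    fitted amplitude >= ``snr_min * noise_sd``.  Candidates closer than
    ``min_separation`` (default ``2 * psf_sigma_guess``) keep the brighter
    fit.  A blank frame returns an empty list.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    bg, noise = robust_background(frame)
    if min_separation is None:
        min_separation = 2.0 * psf_sigma_guess

    smooth = ndimage.gaussian_filter(frame, sigma=psf_sigma_guess)
    maxfilt = ndimage.maximum_filter(smooth, size=3, mode="nearest")
    is_max = (smooth == maxfilt) & (frame > bg + snr_min * noise)
    cand_y, cand_x = np.nonzero(is_max)
    if cand_y.size == 0:
        return []

    # resolve candidate clusters: keep the brightest within min_separation
    order = np.argsort(frame[cand_y, cand_x])[::-1]
    kept: list[tuple[int, int]] = []
    for i in order:
        x, y = int(cand_x[i]), int(cand_y[i])
        if all((x - kx) ** 2 + (y - ky) ** 2 >= min_separation**2 for kx, ky in kept):
            kept.append((x, y))

    H, W = frame.shape
    spots: list[Spot] = []
    for cx, cy in kept:
        fit = _fit_spot(frame, cx, cy, psf_sigma_guess, window, bg)
        if fit is None:
            continue
        (amp, x0, y0, sigma, offset), rms, ok, x_sd = fit
        if not ok or amp < snr_min * noise:
            continue
        if sigma <= 0.5 * psf_sigma_guess + 1e-9 or sigma >= 3.0 * psf_sigma_guess - 1e-9:
            continue
        if not (0 <= x0 < W and 0 <= y0 < H):
            continue
        # a clearly inflated sigma is the signature of two partially
        # overlapping particles; try resolving them with a two-emitter refit
        if two_emitter and sigma > 1.3 * psf_sigma_guess:
            split = _try_split(
                frame, x0, y0, psf_sigma_guess, bg, window, snr_min * noise, W, H
            )
            if split is not None:
                spots.extend(split)
                continue
        spots.append(
            Spot(
                frame=0,
                x=float(x0),
                y=float(y0),
                sigma=float(sigma),
                integrated_intensity=float(2.0 * np.pi * amp * sigma**2),
                local_background=float(offset),
                fit_uncertainty=x_sd,
            )
        )
    # post-fit dedupe: two windows may converge onto the same molecule
    spots.sort(key=lambda s: -s.integrated_intensity)
    final: list[Spot] = []
    for s in spots:
        if all((s.x - f.x) ** 2 + (s.y - f.y) ** 2 >= 1.0 for f in final):
            final.append(s)
    return final


def detect_stack(
    stack: ImageStack,
    psf_sigma_guess: float = 1.1,
    snr_min: float = 4.0,
    window: int = 9,
) -> list[list[Spot]]:
    """Run :func:`detect_spots` on every frame, stamping frame indices."""
    per_frame: list[list[Spot]] = []
    for f in range(stack.n_frames):
        spots = detect_spots(stack.frames[f], psf_sigma_guess, snr_min, window)
        for s in spots:
            s.frame = f
        per_frame.append(spots)
    return per_frame
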