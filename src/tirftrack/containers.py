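"""Core in-memory containers shared across the pipeline.

Coordinate convention (used everywhere in this package): pixel coordinates are
0-based with the origin at the *center* of the top-left pixel, ``x`` along
image columns and ``y`` along rows.  Physical lengths are micrometres
(``pixel_size`` converts px -> µm), time is seconds, intensities are ADU
(camera analog-to-digital units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageStack",
    "Spot",
    "Track",
    "MicrotubulePath",
    "Projected1DTrack",
    "DiffusionEstimate",
    "BindingMeasurement",
    "OligomerCall",
]


@dataclass
class ImageStack:
    """Calibrated multi-frame pixel data for a single channel.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, H, W)``.
    channel
        Role of this channel: ``"microtubule"`` or ``"complex"``.
    pixel_size
        µm per pixel.
    dt
        Seconds per frame.
    """

    frames: np.ndarray
    channel: str = "complex"
    pixel_size: float = 0.13
    dt: float = 0.113

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (n_frames, H, W); got shape {self.frames.shape}")
        if self.pixel_size <= 0 or self.dt <= 0:
            raise ValueError("pixel_size and dt must be positive")
        if self.channel not in ("microtubule", "complex"):
            raise ValueError(f"unknown channel role {self.channel!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class Spot:
    """A single sub-pixel localization from a 2D Gaussian fit."""

    frame: int
    x: float
    y: float
    sigma: float
    integrated_intensity: float  # background-subtracted Gaussian volume, ADU
    local_background: float      # ADU / px
    fit_uncertainty: float = np.nan  # px, from the fit covariance


@dataclass
class Track:
    """Time-ordered spots belonging to one particle.

    Frame indices are strictly increasing; missing frames (gaps) are simply
    absent from ``spots``.
    """

    track_id: int
    spots: list[Spot] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = self.frames
        if len(frames) > 1 and np.any(np.diff(frames) <= 0):
            raise ValueError("track frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots], dtype=int)

    @property
    def xy(self) -> np.ndarray:
        """Positions as an ``(n, 2)`` array of (x, y) in px."""
        return np.array([[s.x, s.y] for s in self.spots], dtype=float).reshape(-1, 2)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([s.integrated_intensity for s in self.spots], dtype=float)


class MicrotubulePath:
    """An ordered polyline along a microtubule with arclength parametrization.

    Parameters
    ----------
    points
        ``(n, 2)`` array of (x, y) pixel coordinates, ordered along the
        filament; at least two points.
    pixel_size
        µm per px, used to express arclength in µm.
    width
        Apparent filament width estimate in px (for QC / kymograph defaults).
    """

    def __init__(self, points: np.ndarray, pixel_size: float = 0.13, width: float = 3.0):
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        if points.shape[0] < 2:
            raise ValueError("a path needs at least two points")
        seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
        if np.any(seglen == 0):
            keep = np.concatenate([[True], seglen > 0])
            points = points[keep]
            seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
            if points.shape[0] < 2:
                raise ValueError("degenerate path: zero total length")
        self.points = points
        self.pixel_size = float(pixel_size)
        self.width = float(width)
        # cumulative arclength in µm, strictly increasing
        self.arclength = np.concatenate([[0.0], np.cumsum(seglen)]) * self.pixel_size

    @property
    def length(self) -> float:
        """Total arclength in µm."""
        return float(self.arclength[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Interpolate (x, y) px at arclength(s) ``s`` in µm."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        x = np.interp(s, self.arclength, self.points[:, 0])
        y = np.interp(s, self.arclength, self.points[:, 1])
        return np.stack([x, y], axis=-1)

    def tangent_at(self, s: float | np.ndarray) -> np.ndarray:
        """Unit tangent vector(s) at arclength ``s`` (µm)."""
        eps = max(self.pixel_size, 1e-6)
        s = np.asarray(s, dtype=float)
        p0 = self.point_at(np.maximum(s - eps, 0.0))
        p1 = self.point_at(np.minimum(s + eps, self.length))
        d = p1 - p0
        n = np.linalg.norm(d, axis=-1, keepdims=True)
        n[n == 0] = 1.0
        return d / n

    def project(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project 2D pixel positions onto the path.

        Returns ``(s, r)``: arclength of the nearest path point (µm) and the
        signed perpendicular residual (µm).  Projection is onto the polyline's
        segments (exact foot-point, not just nearest vertex).
        """
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        a = self.points[:-1]              # (m, 2) segment starts
        b = self.points[1:]               # (m, 2) segment ends
        ab = b - a
        ab2 = np.sum(ab**2, axis=1)       # (m,)
        # (n, m) projections of each point on each segment
        ap = xy[:, None, :] - a[None, :, :]
        t = np.clip(np.einsum("nmd,md->nm", ap, ab) / ab2[None, :], 0.0, 1.0)
        foot = a[None, :, :] + t[..., None] * ab[None, :, :]
        d2 = np.sum((xy[:, None, :] - foot) ** 2, axis=2)
        j = np.argmin(d2, axis=1)
        idx = np.arange(xy.shape[0])
        tbest = t[idx, j]
        footb = foot[idx, j]
        s_px = (self.arclength[j] / self.pixel_size) + tbest * np.sqrt(ab2[j])
        # signed residual: cross product of tangent with (point - foot)
        tang = ab[j] / np.sqrt(ab2[j])[:, None]
        diff = xy - footb
        r_px = tang[:, 0] * diff[:, 1] - tang[:, 1] * diff[:, 0]
        return s_px * self.pixel_size, r_px * self.pixel_size


@dataclass
class Projected1DTrack:
    """A track reduced to 1D motion along a (possibly averaged) path."""

    track_id: int
    s: np.ndarray          # arclength positions, µm
    frames: np.ndarray     # frame indices matching s
    residuals: np.ndarray  # signed perpendicular residuals, µm
    dt: float              # s per frame

    def displacements(self) -> np.ndarray:
        """Single-frame displacements, excluding any gap-spanning steps."""
        ds = np.diff(self.s)
        dframe = np.diff(self.frames)
        return ds[dframe == 1]

    def contiguous_runs(self) -> list[np.ndarray]:
        """Arclength positions split into gap-free runs."""
        breaks = np.where(np.diff(self.frames) != 1)[0] + 1
        return np.split(self.s, breaks)


@dataclass
class DiffusionEstimate:
    """Per-track 1D diffusion estimate with localization-noise correction.

    ``D_hat`` may be negative for short/noisy tracks: the estimator is
    unbiased, not positivity-constrained, and summaries use medians.
    """

    track_id: int
    D_hat: float           # µm²/s
    sigma2_loc_hat: float  # µm²
    R: float               # motion-blur coefficient, in [0, 1/4]
    n_steps: int
    motility_class: str = "unclassified"  # static | diffusive | unclassified
    valid: bool = True     # False => too short, excluded from summaries


@dataclass
class BindingMeasurement:
    """Background-corrected mean intensity over one microtubule area."""

    condition: dict[str, float]  # species -> nM
    microtubule_id: int
    mean_bc_intensity: float     # ADU / px
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels <= 0:
            raise ValueError("n_pixels must be positive")
        if any(v < 0 for v in self.condition.values()):
            raise ValueError("condition concentrations must be >= 0")


@dataclass
class OligomerCall:
    """Molecule count for one track from intensity / single-molecule unit."""

    track_id: int
    mean_integrated_intensity: float  # ADU, first-window average
    unit_intensity: float             # ADU per fluorophore
    n_molecules: float                # ratio, as reported
    n_rounded: int                    # nearest integer, >= 1

    @classmethod
    def from_intensity(cls, track_id: int, intensity: float, unit: float) -> "OligomerCall":
        if unit <= 0:
            raise ValueError("unit_intensity must be positive")
        ratio = intensity / unit
        return cls(track_id, intensity, unit, ratio, max(1, int(round(ratio))))
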