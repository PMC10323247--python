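"""Microtubule segmentation from the filament channel, and kymographs.

Manual ROI drawing is replaced by automated segmentation: the time-averaged
microtubule image is thresholded (robust background + k sigma), skeletonized,
and each sufficiently long skeleton branch becomes an ordered
:class:`~tirftrack.containers.MicrotubulePath`.  Each path carries a dilated
binary mask (``path.mask``) defining the "area around the microtubule" used
for intensity quantification.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .containers import ImageStack, MicrotubulePath
from .detect import robust_background

__all__ = ["segment_microtubules", "make_kymograph"]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _order_skeleton(coords: set[tuple[int, int]]) -> list[tuple[int, int]] | None:
    """Order skeleton pixels (row, col) by walking from an endpoint."""

    def neighbors(p: tuple[int, int]) -> list[tuple[int, int]]:
        return [(p[0] + dy, p[1] + dx) for dy, dx in _NEIGHBORS if (p[0] + dy, p[1] + dx) in coords]

    endpoints = [p for p in coords if len(neighbors(p)) == 1]
    start = endpoints[0] if endpoints else next(iter(coords))
    path = [start]
    visited = {start}
    cur = start
    while True:
        nxt = [p for p in neighbors(cur) if p not in visited]
        if not nxt:
            break
        # prefer 4-connected continuation to keep steps short
        nxt.sort(key=lambda p: abs(p[0] - cur[0]) + abs(p[1] - cur[1]))
        cur = nxt[0]
        path.append(cur)
        visited.add(cur)
    if len(path) < 2:
        return None
    return path


def segment_microtubules(
    mt_stack: ImageStack,
    min_length: float = 10.0,
    snr_threshold: float = 5.0,
    dilation_radius: int = 4,
    smooth_window: int = 5,
) -> list[MicrotubulePath]:
    """Segment microtubule paths from the microtubule channel.

    Parameters
    ----------
    mt_stack
        Microtubule-channel stack; frames are time-averaged first.
    min_length
        Minimum skeleton length in px for a filament to be kept.
    snr_threshold
        Threshold in robust noise SDs above the median background.
    dilation_radius
        Radius (px) of the dilated per-filament mask stored as ``path.mask``.
    smooth_window
        Moving-average window (points) applied to the skeleton polyline to
        suppress pixel-level jaggedness.

    Returns an empty list (with a warning) if nothing is found.
    """
    if mt_stack.channel != "microtubule":
        raise ValueError("segment_microtubules expects the microtubule channel")
    avg = mt_stack.frames.mean(axis=0).astype(float)
    bg, noise = robust_background(avg)
    mask = avg > bg + snr_threshold * max(noise, 1e-12)
    mask = ndimage.binary_closing(mask, structure=np.ones((3, 3)))
    if not mask.any():
        warnings.warn("no microtubule found in channel", stacklevel=2)
        return []
    skel = skeletonize(mask)
    labels, n = ndimage.label(skel, structure=np.ones((3, 3)))
    paths: list[MicrotubulePath] = []
    for lab in range(1, n + 1):
        coords = set(zip(*np.nonzero(labels == lab)))
        if len(coords) < max(2, int(min_length)):
            continue
        ordered = _order_skeleton(coords)
        if ordered is None or len(ordered) < max(2, int(min_length)):
            continue
        pts = np.array([(c, r) for r, c in ordered], dtype=float)  # (x, y)
        if smooth_window > 1 and len(pts) > smooth_window:
            kernel = np.ones(smooth_window) / smooth_window
            sm = np.empty_like(pts)
            for d in range(2):
                sm[:, d] = np.convolve(pts[:, d], kernel, mode="same")
            # moving-average edge effects: keep raw endpoints
            h = smooth_window // 2
            sm[:h] = pts[:h]
            sm[-h:] = pts[-h:]
            pts = sm
        comp_mask = labels == lab
        dil = ndimage.binary_dilation(
            comp_mask, structure=np.ones((3, 3)), iterations=dilation_radius
        )
        area = float(np.count_nonzero(ndimage.binary_dilation(comp_mask)))
        path = MicrotubulePath(
            pts, pixel_size=mt_stack.pixel_size, width=area / max(len(coords), 1)
        )
        path.mask = dil  # type: ignore[attr-defined]
        paths.append(path)
    if not paths:
        warnings.warn("no microtubule path above min_length", stacklevel=2)
    return paths


def make_kymograph(
    stack: ImageStack,
    path: MicrotubulePath,
    width: int = 5,
    reducer: str = "max",
) -> np.ndarray:
    """Build a (time x arclength) kymograph along a microtubule path.

    Each row t samples the stack frame along the path at 1 px arclength steps;
    at every arclength sample, ``width`` positions spaced 1 px along the local
    normal are read by bilinear interpolation and reduced by ``max`` (default)
    or ``mean``.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if reducer not in ("max", "mean"):
        raise ValueError("reducer must be 'max' or 'mean'")
    step_um = stack.pixel_size  # 1 px arclength steps
    s = np.arange(0.0, path.length + 0.5 * step_um, step_um)
    centers = path.point_at(s)                # (n_s, 2) x,y
    tangents = path.tangent_at(s)             # (n_s, 2)
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    # sample grid: (n_s, width, 2)
    pts = centers[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    coords = np.stack([pts[..., 1].ravel(), pts[..., 0].ravel()])  # rows=y, cols=x

    kymo = np.empty((stack.n_frames, len(s)), dtype=float)
    for f in range(stack.n_frames):
        vals = ndimage.map_coordinates(
            stack.frames[f].astype(float), coords, order=1, mode="nearest"
        ).reshape(len(s), width)
        kymo[f] = vals.max(axis=1) if reducer == "max" else vals.mean(axis=1)
    return kymo
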