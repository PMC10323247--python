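"""Intensity quantification: binding measurements and molecule counting.

The binding readout follows the standard TIRF dose-response recipe: the mean
complex-channel intensity over each microtubule area, minus the mean over a
nearby background region (by default an annulus around the dilated filament
mask, excluding all filament masks), yields one background-corrected data
point per microtubule.  Molecule counting divides each track's mean
integrated intensity (first 20 frames) by the single-fluorophore unit
intensity calibrated from single-step photobleaching traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import BindingMeasurement, ImageStack, OligomerCall, Track

__all__ = [
    "background_corrected_intensity",
    "track_mean_intensity",
    "detect_steps",
    "CalibrationResult",
    "calibrate_unit_intensity",
    "count_molecules",
]


def background_corrected_intensity(
    stack: ImageStack,
    mt_mask: np.ndarray,
    bg_mask: np.ndarray | None = None,
    all_mt_masks: np.ndarray | None = None,
    condition: dict[str, float] | None = None,
    microtubule_id: int = 0,
    annulus_width: int = 6,
) -> BindingMeasurement:
    """One background-corrected binding data point for one microtubule area.

    Parameters
    ----------
    stack
        Complex-channel stack; frames are time-averaged before measuring.
    mt_mask
        Boolean mask of the microtubule area (already dilated around the
        filament).
    bg_mask
        Explicit background region.  If ``None``, an annulus of
        ``annulus_width`` px around ``mt_mask`` is used, excluding
        ``all_mt_masks`` (union of every microtubule area in the field) so
        that neighbouring filaments do not contaminate the background.
    """
    if mt_mask.dtype != bool:
        mt_mask = mt_mask.astype(bool)
    if not mt_mask.any():
        raise ValueError("mt_area mask is empty")
    img = stack.frames.mean(axis=0).astype(float)
    if img.shape != mt_mask.shape:
        raise ValueError("mask shape does not match stack frames")

    if bg_mask is None:
        exclude = mt_mask if all_mt_masks is None else (all_mt_masks.astype(bool) | mt_mask)
        ring = ndimage.binary_dilation(
            mt_mask, structure=np.ones((3, 3)), iterations=annulus_width
        )
        bg_mask = ring & ~exclude
    else:
        bg_mask = bg_mask.astype(bool)
        if (bg_mask & mt_mask).any():
            raise ValueError("mt_area and bg_area masks must be disjoint")
    if not bg_mask.any():
        raise ValueError(
            "background region is empty; supply bg_mask explicitly "
            "(the automatic annulus was fully covered by microtubule areas)"
        )
    value = float(img[mt_mask].mean() - img[bg_mask].mean())
    return BindingMeasurement(
        condition=dict(condition or {}),
        microtubule_id=microtubule_id,
        mean_bc_intensity=value,
        n_pixels=int(mt_mask.sum()),
    )


def track_mean_intensity(track: Track, n_first: int = 20) -> float:
    """Mean integrated intensity over the earliest ``n_first`` frames of a track."""
    if len(track) < 1:
        raise ValueError("track is empty")
    return float(track.intensities[: min(n_first, len(track))].mean())


def _best_split(x: np.ndarray, min_seg: int) -> tuple[int, float] | None:
    """Best single changepoint of a piecewise-constant fit; (index, RSS gain)."""
    n = len(x)
    if n < 2 * min_seg:
        return None
    total = float(np.sum((x - x.mean()) ** 2))
    csum = np.cumsum(x)
    csum2 = np.cumsum(x**2)
    ks = np.arange(min_seg, n - min_seg + 1)
    left_rss = csum2[ks - 1] - csum[ks - 1] ** 2 / ks
    right_n = n - ks
    right_sum = csum[-1] - csum[ks - 1]
    right_sum2 = csum2[-1] - csum2[ks - 1]
    right_rss = right_sum2 - right_sum**2 / right_n
    rss = left_rss + right_rss
    j = int(np.argmin(rss))
    return int(ks[j]), total - float(rss[j])


def detect_steps(
    trace: np.ndarray, noise_sd: float | None = None, min_seg: int = 3
) -> list[int]:
    """Changepoints of a piecewise-constant trace by penalized binary segmentation.

    Splits greedily, accepting a split while the residual-sum-of-squares gain
    exceeds a BIC-style penalty ``2 log(n) sigma^2`` (two extra parameters per
    step: a level and a location).  ``noise_sd`` defaults to a robust estimate
    from first differences (MAD / sqrt(2)).
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < 2 * min_seg:
        return []
    if noise_sd is None:
        d = np.diff(trace)
        noise_sd = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)
    # numerical floor keeps exactly-piecewise-constant traces from splitting
    # on cumsum rounding error
    floor = 1e-9 * float(np.sum(trace**2)) / n + 1e-30
    penalty = max(2.0 * np.log(n) * max(noise_sd, 1e-12) ** 2, floor)

    changepoints: list[int] = []
    segments = [(0, n)]
    while segments:
        lo, hi = segments.pop()
        found = _best_split(trace[lo:hi], min_seg)
        if found is None:
            continue
        k, gain = found
        if gain <= penalty:
            continue
        cp = lo + k
        changepoints.append(cp)
        segments.append((lo, cp))
        segments.append((cp, hi))
    return sorted(changepoints)


@dataclass
class CalibrationResult:
    """Single-fluorophore unit intensity from photobleaching traces."""

    unit_intensity: float   # ADU, mean pre-bleach plateau of accepted traces
    n_accepted: int
    n_traces: int
    low_confidence: bool    # True when fewer than 20 traces were accepted

    def __float__(self) -> float:
        return self.unit_intensity


def calibrate_unit_intensity(
    traces: list[np.ndarray] | np.ndarray,
    noise_sd: float | None = None,
    min_accepted: int = 20,
) -> CalibrationResult:
    """Calibrate the single-fluorophore intensity from bleaching traces.

    A trace is accepted as a single fluorophore iff changepoint detection
    finds exactly one (downward) step and the terminal level is consistent
    with background (|level| < 2 x noise SD).  The unit is the mean pre-step
    plateau over accepted traces.  Emits a warning and flags the result when
    fewer than ``min_accepted`` traces survive.
    """
    plateaus: list[float] = []
    traces = list(traces)
    for tr in traces:
        tr = np.asarray(tr, dtype=float)
        sd = noise_sd
        if sd is None:
            d = np.diff(tr)
            sd = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)
        steps = detect_steps(tr, noise_sd=sd)
        if len(steps) != 1:
            continue
        cp = steps[0]
        pre = float(tr[:cp].mean())
        post = float(tr[cp:].mean())
        if post >= pre:  # not a bleach
            continue
        if abs(post) >= 2.0 * max(sd, 1e-12):
            continue
        plateaus.append(pre)
    n_acc = len(plateaus)
    low = n_acc < min_accepted
    if low:
        warnings.warn(
            f"only {n_acc} single-step traces accepted (< {min_accepted}); "
            "unit intensity is low-confidence",
            stacklevel=2,
        )
    unit = float(np.mean(plateaus)) if plateaus else float("nan")
    return CalibrationResult(unit, n_acc, len(traces), low)


def count_molecules(
    track_id: int, mean_intensity: float, unit_intensity: float
) -> OligomerCall:
    """Convert a track's mean integrated intensity to a molecule count."""
    return OligomerCall.from_intensity(track_id, mean_intensity, unit_intensity)
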