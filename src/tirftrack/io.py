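"""File formats: multi-page TIFF stacks, track tables, manifests.

Stacks are multi-page TIFF (one file per channel, 8/16-bit unsigned or
32-bit float); track tables are CSV with a fixed schema; experiment manifests
are YAML (JSON-compatible) mapping stacks to channel roles, conditions and
replicate labels.  Units follow the package registry: concentrations nM,
lengths µm, time s, intensities ADU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import ImageStack, Spot, Track

__all__ = [
    "read_stack",
    "write_stack",
    "write_tracks",
    "read_tracks",
    "StackEntry",
    "ExperimentManifest",
]

TRACK_COLUMNS = [
    "track_id",
    "frame",
    "x_px",
    "y_px",
    "sigma_px",
    "integrated_intensity",
    "background",
]

_ALLOWED_DTYPES = (np.uint8, np.uint16, np.float32)


def read_stack(
    path: str | Path,
    channel: str = "complex",
    pixel_size: float = 0.13,
    dt: float = 0.113,
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Metadata (channel role, pixel size, frame interval) comes from the
    caller / manifest, overriding anything embedded in the file.  All pages
    must share one shape; 16-bit data round-trips bit-identically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
    if not pages:
        raise ValueError(f"empty TIFF: {path}")
    shape0 = pages[0].shape
    for i, p in enumerate(pages):
        if p.shape != shape0:
            raise ValueError(f"page {i} shape {p.shape} != page 0 shape {shape0} in {path}")
    frames = np.stack(pages)
    if frames.dtype not in [np.dtype(d) for d in _ALLOWED_DTYPES]:
        raise ValueError(f"unsupported TIFF dtype {frames.dtype} (use uint8/uint16/float32)")
    return ImageStack(frames, channel=channel, pixel_size=pixel_size, dt=dt)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF (one channel per file)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = stack.frames
    if frames.dtype not in [np.dtype(d) for d in _ALLOWED_DTYPES]:
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack")


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    """Write tracks to CSV (schema: track_id, frame, x_px, y_px, sigma_px,
    integrated_intensity, background); an empty list writes a header-only file."""
    rows = []
    for tr in tracks:
        for sp in tr.spots:
            rows.append(
                (tr.track_id, sp.frame, sp.x, sp.y, sp.sigma,
                 sp.integrated_intensity, sp.local_background)
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df = df.sort_values(["track_id", "frame"], kind="stable")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[Track]:
    """Read a track CSV back into Track objects (stable-sorted, validated)."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV missing columns: {missing}")
    if len(df) == 0:
        return []
    if not df[["track_id", "frame"]].equals(
        df[["track_id", "frame"]].sort_values(["track_id", "frame"], kind="stable")
    ):
        warnings.warn("track CSV rows out of order; re-sorting", stacklevel=2)
        df = df.sort_values(["track_id", "frame"], kind="stable")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        spots = [
            Spot(
                frame=int(r.frame), x=float(r.x_px), y=float(r.y_px),
                sigma=float(r.sigma_px),
                integrated_intensity=float(r.integrated_intensity),
                local_background=float(r.background),
            )
            for r in g.itertuples()
        ]
        tracks.append(Track(track_id=int(tid), spots=spots))
    return tracks


@dataclass
class StackEntry:
    """One stack file in a manifest."""

    path: str
    channel: str                      # "complex" | "microtubule"
    condition: dict[str, float] = field(default_factory=dict)  # species -> nM
    replicate: str = "rep1"
    group: str | None = None          # stacks sharing a group form one field of view


@dataclass
class ExperimentManifest:
    """Declares the stacks, conditions and calibration of one experiment."""

    stacks: list[StackEntry]
    pixel_size: float = 0.13
    dt: float = 0.113

    def __post_init__(self) -> None:
        for e in self.stacks:
            if not e.replicate:
                raise ValueError("replicate labels must be non-empty")
            if e.channel not in ("complex", "microtubule"):
                raise ValueError(f"bad channel role {e.channel!r} for {e.path}")
        for g, entries in self.grouped().items():
            n_complex = sum(1 for e in entries if e.channel == "complex")
            if n_complex != 1:
                raise ValueError(f"group {g!r} must have exactly one complex channel")

    def grouped(self) -> dict[str, list[StackEntry]]:
        groups: dict[str, list[StackEntry]] = {}
        for e in self.stacks:
            groups.setdefault(e.group or e.path, []).append(e)
        return groups

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentManifest":
        d = yaml.safe_load(Path(path).read_text())
        stacks = [StackEntry(**s) for s in d["stacks"]]
        return cls(stacks=stacks, pixel_size=d.get("pixel_size", 0.13), dt=d.get("dt", 0.113))

    def save(self, path: str | Path) -> None:
        d = {
            "pixel_size": self.pixel_size,
            "dt": self.dt,
            "stacks": [
                {
                    "path": e.path, "channel": e.channel,
                    "condition": {k: float(v) for k, v in e.condition.items()},
                    "replicate": e.replicate, "group": e.group,
                }
                for e in self.stacks
            ],
        }
        Path(path).write_text(yaml.safe_dump(d))
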