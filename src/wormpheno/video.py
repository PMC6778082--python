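"""Video clip container and TIFF round-trip.

A clip is one 10 s recording of a single growth chamber at one time point:
a stack of grayscale frames plus the calibration (frame rate, pixel size)
and provenance (worm id, compound concentration, hours post-hatch) needed
to interpret it downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass(frozen=True)
class ClipMeta:
    """Provenance of one clip.

    condition_mol is the compound concentration in mol/L; 0.0 denotes the
    control. time_h is hours post-hatch.
    """

    worm_id: str = "worm0"
    condition_mol: float = 0.0
    time_h: float = 0.0


@dataclass
class VideoClip:
    """Grayscale frame stack with calibration.

    frames: (n_frames, H, W) float array on [0, 1].
    fps: frames per second (> 0).
    px_um: microns per pixel (> 0).
    """

    frames: np.ndarray
    fps: float
    px_um: float
    meta: ClipMeta = field(default_factory=ClipMeta)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("clip needs >= 2 frames of identical shape")
        if self.fps <= 0 or self.px_um <= 0:
            raise ValueError("fps and px_um must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def write_clip_tiff(clip: VideoClip, path: str | Path) -> None:
    """Write a clip as a 16-bit multi-page TIFF (intensities scaled from [0,1])."""
    data = np.clip(clip.frames, 0.0, 1.0)
    stack = np.round(data * 65535.0).astype(np.uint16)
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_clip_images(
    paths: list[str | Path],
    fps: float,
    px_um: float,
    meta: ClipMeta | None = None,
) -> VideoClip:
    """Read a numbered grayscale image sequence (PNG/TIFF/... one file per
    frame, in the given order) as one clip; integer data is rescaled to
    [0, 1] and RGB frames are averaged to grayscale."""
    import imageio.v3 as iio

    frames = []
    for p in paths:
        img = np.asarray(iio.imread(str(p)))
        if img.ndim == 3:  # RGB(A) -> grayscale
            img = img[..., :3].mean(axis=-1)
        if np.issubdtype(img.dtype, np.integer):
            img = img.astype(np.float64) / np.iinfo(img.dtype).max
        frames.append(img.astype(np.float32))
    return VideoClip(
        frames=np.stack(frames), fps=fps, px_um=px_um, meta=meta or ClipMeta()
    )


def read_clip_tiff(
    path: str | Path,
    fps: float,
    px_um: float,
    meta: ClipMeta | None = None,
) -> VideoClip:
    """Read a multi-page TIFF written by :func:`write_clip_tiff` (or any
    grayscale stack; 8/16-bit integer data is rescaled to [0, 1])."""
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    if np.issubdtype(stack.dtype, np.integer):
        stack = stack.astype(np.float64) / np.iinfo(stack.dtype).max
    return VideoClip(
        frames=stack.astype(np.float32),
        fps=fps,
        px_um=px_um,
        meta=meta or ClipMeta(),
    )
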