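"""Frame-to-mask segmentation for single-worm chamber clips.

The worm is the only moving dark object in a brightfield chamber whose
static structures (walls, pillars, filters) are captured by a per-pixel
temporal background estimate. Each frame is segmented on the difference
image background - frame (the worm is darker than the background), with
an automatic threshold, light morphology, and a largest-component rule —
one worm per chamber by design, so the largest dark component is the worm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .video import VideoClip  # re-export: clips enter the pipeline here

__all__ = [
    "VideoClip",
    "SegmentationOptions",
    "WormMask",
    "Background",
    "estimate_background",
    "segment_frame",
    "segment_clip",
]


@dataclass(frozen=True)
class SegmentationOptions:
    """Tunables for frame segmentation.

    threshold: fixed threshold on the difference image, or None for the
        automatic rule. The automatic rule is Otsu's method on the
        difference histogram, floored at half the robust worm-background
        contrast (the half-maximum contour of a blur-limited object is its
        unbiased boundary, whereas a low Otsu split dilates thin worms).
    background_percentile: temporal percentile used as the background. The
        worm is darker than the chamber, so a high percentile recovers the
        empty-chamber intensity even under a pixel the (slow) worm occupies
        in most frames; 50 reproduces a plain temporal median.
    min_area_px: components smaller than this are treated as empty frames.
    min_contrast: if the robust contrast of the difference image (mean of
        its top `contrast_topk` pixels) stays below this, the frame is
        declared empty outright.
    """

    threshold: float | None = None
    background_percentile: float = 90.0
    opening_radius_px: int = 1
    closing_radius_px: int = 2
    min_area_px: int = 30
    min_contrast: float = 0.08
    contrast_topk: int = 200


@dataclass
class MaskQC:
    empty: bool = False
    touching_border: bool = False
    multi_component_resolved: bool = False


@dataclass
class WormMask:
    """Binary worm mask for one frame with centroid (µm) and area (µm²)."""

    mask: np.ndarray
    px_um: float
    qc: MaskQC = field(default_factory=MaskQC)

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.px_um ** 2

    @property
    def centroid_um(self) -> tuple[float, float] | None:
        """(x, y) µm centroid, None for an empty mask."""
        if not self.mask.any():
            return None
        cm = ndimage.center_of_mass(self.mask)
        return (float(cm[1]) * self.px_um, float(cm[0]) * self.px_um)


@dataclass
class Background:
    image: np.ndarray
    fallback: bool = False  # True when too few frames for a temporal estimate


def estimate_background(
    clip: VideoClip, percentile: float = 90.0
) -> Background:
    """Per-pixel temporal percentile across frames (default 90th).

    The worm occupies any given pixel in a minority of frames of a 10 s
    clip; because it is darker than the chamber, a high temporal
    percentile recovers the empty-chamber intensity there even when a
    slow worm lingers, while static structures survive unchanged.
    `percentile=50` gives the plain temporal median. With fewer than 3
    frames the first frame is returned with a fallback flag.
    """
    if clip.n_frames < 3:
        warnings.warn(
            "fewer than 3 frames: using first frame as background", stacklevel=2
        )
        return Background(image=np.asarray(clip.frames[0], dtype=np.float64),
                          fallback=True)
    bg = np.percentile(np.asarray(clip.frames, dtype=np.float64), percentile, axis=0)
    return Background(image=bg)


def _robust_contrast(diff: np.ndarray, topk: int) -> float:
    flat = diff.ravel()
    k = min(topk, flat.size)
    top = np.partition(flat, flat.size - k)[flat.size - k:]
    return float(top.mean())


def segment_frame(
    frame: np.ndarray,
    background: np.ndarray,
    px_um: float,
    opts: SegmentationOptions | None = None,
) -> WormMask:
    """Segment one frame against a background estimate.

    Pipeline: diff = clip(background - frame, 0); threshold (see
    SegmentationOptions); opening (radius 1) then closing (radius 2);
    largest connected component; hole filling. An all-background frame
    yields an empty mask with qc.empty set, never an exception.
    """
    opts = opts or SegmentationOptions()
    frame = np.asarray(frame, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    diff = np.clip(background - frame, 0.0, None)

    qc = MaskQC()
    empty = WormMask(mask=np.zeros(frame.shape, dtype=bool), px_um=px_um, qc=qc)
    contrast = _robust_contrast(diff, opts.contrast_topk)
    if contrast < opts.min_contrast:
        qc.empty = True
        return empty

    if opts.threshold is not None:
        thr = opts.threshold
    else:
        try:
            thr = float(threshold_otsu(diff))
        except ValueError:  # constant image
            thr = 0.5 * contrast
        # Otsu's split on a histogram dominated by background zeros can sit
        # well below half contrast, dilating the apparent worm; the
        # half-maximum contour is the unbiased boundary under symmetric blur.
        thr = max(thr, 0.5 * contrast)

    binary = diff > thr
    if not binary.any():
        qc.empty = True
        return empty

    # morphology restricted to the active bounding box for speed
    rows, cols = np.nonzero(binary)
    pad = 2 * (opts.opening_radius_px + opts.closing_radius_px) + 2
    r0 = max(rows.min() - pad, 0)
    r1 = min(rows.max() + pad + 1, binary.shape[0])
    c0 = max(cols.min() - pad, 0)
    c1 = min(cols.max() + pad + 1, binary.shape[1])
    sub = binary[r0:r1, c0:c1]
    # edge-replicated pad so objects cut by the frame border are not eroded
    m = pad
    sub = np.pad(sub, m, mode="edge")
    if opts.opening_radius_px > 0:
        sub = ndimage.binary_opening(sub, structure=disk(opts.opening_radius_px))
    if opts.closing_radius_px > 0:
        sub = ndimage.binary_closing(sub, structure=disk(opts.closing_radius_px))
    sub = sub[m:-m, m:-m]

    labels, n_lab = ndimage.label(sub)
    if n_lab == 0:
        qc.empty = True
        return empty
    counts = np.bincount(labels.ravel())[1:]
    if n_lab > 1:
        qc.multi_component_resolved = True
    best = int(np.argmax(counts)) + 1
    if counts[best - 1] < opts.min_area_px:
        qc.empty = True
        return empty
    sub_mask = ndimage.binary_fill_holes(labels == best)
    mask = np.zeros(frame.shape, dtype=bool)
    mask[r0:r1, c0:c1] = sub_mask

    if (
        mask[0, :].any() or mask[-1, :].any()
        or mask[:, 0].any() or mask[:, -1].any()
    ):
        qc.touching_border = True
    return WormMask(mask=mask, px_um=px_um, qc=qc)


@dataclass
class ClipSegmentation:
    masks: list[WormMask]
    background: Background
    qc_failed: bool  # > 50% empty frames

    @property
    def n_empty(self) -> int:
        return sum(m.qc.empty for m in self.masks)


def export_masks_tiff(seg: "ClipSegmentation", path) -> None:
    """Audit export: the per-frame binary masks as an 8-bit multi-page TIFF
    (255 = worm)."""
    import tifffile

    stack = np.stack([m.mask for m in seg.masks]).astype(np.uint8) * 255
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def segment_clip(
    clip: VideoClip,
    opts: SegmentationOptions | None = None,
    background: np.ndarray | None = None,
) -> ClipSegmentation:
    """Segment every frame of a clip.

    The background defaults to the clip's own temporal-percentile estimate;
    a wormless reference frame (e.g. imaged before worm placement, or known
    for a synthetic chamber) can be supplied instead, which is the only way
    to segment a worm that never moves. Empty frames are carried as gaps
    (downstream kinematics bridges them by dividing displacements by the
    actual time gap); a clip with more than half its frames empty is
    flagged as a clip-level QC failure.
    """
    opts = opts or SegmentationOptions()
    if background is not None:
        bg = Background(image=np.asarray(background, dtype=np.float64))
    else:
        bg = estimate_background(clip, percentile=opts.background_percentile)
    masks = [
        segment_frame(f, bg.image, clip.px_um, opts) for f in clip.frames
    ]
    n_empty = sum(m.qc.empty for m in masks)
    return ClipSegmentation(
        masks=masks, background=bg, qc_failed=n_empty > 0.5 * len(masks)
    )
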