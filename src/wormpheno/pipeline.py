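"""Clip-level convenience pipeline: segment -> centerline -> phenotypes."""

from __future__ import annotations

import numpy as np

from .centerline import extract_centerline, orient_clip
from .phenotypes import MIN_FRAMES_DEFAULT, PhenotypeRecord, phenotype_clip
from .segmentation import SegmentationOptions, segment_clip
from .video import VideoClip


def analyze_clip(
    clip: VideoClip,
    seg_opts: SegmentationOptions | None = None,
    background: np.ndarray | None = None,
    K: int = 101,
    smooth: float = 1.0,
    min_frames: int = MIN_FRAMES_DEFAULT,
) -> PhenotypeRecord:
    """Run the full per-clip pipeline and return its PhenotypeRecord.

    `background` optionally supplies a wormless reference frame (needed for
    worms that barely move; otherwise the clip's own temporal percentile is
    used). Frames whose segmentation is empty or whose centerline
    extraction fails (coiled, degenerate) are carried as gaps; a clip
    failing clip-level QC (too many empty frames, too few valid
    centerlines) returns a record with absent values and qc.clip_failed
    set.
    """
    seg = segment_clip(clip, seg_opts, background=background)
    meta = clip.meta
    record = PhenotypeRecord(
        worm_id=meta.worm_id,
        condition_mol=meta.condition_mol,
        time_h=meta.time_h,
    )
    if seg.qc_failed:
        record.qc.clip_failed = True
        record.qc.notes.append("clip QC failure: > 50% empty frames")
        return record

    centerlines = []
    centroids = np.full((clip.n_frames, 2), np.nan)
    for i, wm in enumerate(seg.masks):
        if wm.qc.empty:
            centerlines.append(None)
            continue
        try:
            cl = extract_centerline(wm, K=K, smooth=smooth)
        except ValueError:
            centerlines.append(None)
            continue
        if cl.qc.coiled:
            centerlines.append(None)
            continue
        centerlines.append(cl)
        centroids[i] = wm.centroid_um

    n_valid = sum(cl is not None for cl in centerlines)
    if n_valid < max(2, min_frames):
        record.qc.clip_failed = True
        record.n_valid_frames = n_valid
        record.qc.notes.append(f"only {n_valid} valid centerlines")
        return record

    kin = orient_clip(centerlines, centroids, clip.fps)
    return phenotype_clip(kin, seg.masks, meta, min_frames=min_frames)
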