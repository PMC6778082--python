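"""The six per-clip phenotypes plus the responsiveness criterion.

Per clip (one worm, one time point) the pipeline reports:

* length (µm) — median centerline arclength over valid frames;
* area (µm²) — median mask area over valid frames;
* central velocity (µm/s) — summed centroid displacement between
  consecutive valid frames divided by the spanned time;
* beating frequency (Hz) — thrash count per second from zero crossings of
  the mean-subtracted mid-body bend angle (one thrash = one full bend
  oscillation = two zero crossings), with a hysteresis band suppressing
  noise crossings;
* head and tail beating amplitude (µm) — cumulative path length travelled
  by the head / tail tip over the clip ("total movement"); the peak
  excursion from the mean tip position is emitted as a secondary value.

A worm is *responsive* when the area covered by its travel — the convex
hull of all valid-frame centerline points — exceeds the area of a circle
with radius equal to its body length (pi L^2).

Medians are used for length/area for robustness to the occasional
segmentation outlier. QC failures yield absent values (None), never
zeros, so they cannot drag down downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .centerline import ClipKinematics
from .segmentation import WormMask
from .video import ClipMeta

MIN_FRAMES_DEFAULT = 10
BEND_HYSTERESIS_MAX_RAD = 0.05
BEND_HYSTERESIS_MIN_RAD = 0.02


@dataclass
class PhenotypeQC:
    too_few_frames: bool = False
    orientation_unconfident: bool = False
    freq_unreliable: bool = False  # estimated frequency near the Nyquist limit
    clip_failed: bool = False
    notes: list[str] = field(default_factory=list)


@dataclass
class PhenotypeRecord:
    """Six phenotypes + responsiveness for one worm at one time point.

    Values are None (absent, not zero) when QC fails."""

    worm_id: str
    condition_mol: float
    time_h: float
    length_um: float | None = None
    area_um2: float | None = None
    central_velocity_um_s: float | None = None
    beating_freq_hz: float | None = None
    head_amplitude_um: float | None = None
    tail_amplitude_um: float | None = None
    head_excursion_um: float | None = None
    tail_excursion_um: float | None = None
    responsive: bool | None = None
    n_valid_frames: int = 0
    qc: PhenotypeQC = field(default_factory=PhenotypeQC)

    def to_dict(self) -> dict:
        return {
            "worm_id": self.worm_id,
            "condition_mol": self.condition_mol,
            "time_h": self.time_h,
            "length_um": self.length_um,
            "area_um2": self.area_um2,
            "central_velocity_um_s": self.central_velocity_um_s,
            "beating_freq_hz": self.beating_freq_hz,
            "head_amplitude_um": self.head_amplitude_um,
            "tail_amplitude_um": self.tail_amplitude_um,
            "head_excursion_um": self.head_excursion_um,
            "tail_excursion_um": self.tail_excursion_um,
            "responsive": self.responsive,
            "n_valid_frames": self.n_valid_frames,
            "qc_freq_unreliable": self.qc.freq_unreliable,
            "qc_orientation_unconfident": self.qc.orientation_unconfident,
        }


def length_area(
    kin: ClipKinematics,
    masks: list[WormMask],
    min_frames: int = MIN_FRAMES_DEFAULT,
) -> tuple[float | None, float | None]:
    """Per-clip (length, area): medians over valid frames."""
    idx = np.nonzero(kin.valid)[0]
    if len(idx) < min_frames:
        return None, None
    lengths = [kin.centerlines[i].length_um for i in idx]
    areas = [masks[i].area_um2 for i in idx]
    return float(np.median(lengths)), float(np.median(areas))


def central_velocity(kin: ClipKinematics) -> float | None:
    """Mean centroid speed (µm/s) over consecutive valid frames.

    Gaps from QC-dropped frames are bridged by dividing the displacement by
    the actual spanned time, so a dropped frame does not inflate speed."""
    idx = np.nonzero(kin.valid)[0]
    if len(idx) < 2:
        return None
    pts = kin.centroids_um[idx]
    disp = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    dt = np.diff(idx) / kin.fps
    return float(disp.sum() / dt.sum())


def beating_frequency(
    kin: ClipKinematics,
    hysteresis_rad: float | None = None,
) -> tuple[float | None, bool]:
    """Thrash frequency (Hz) and a Nyquist-reliability flag.

    The mean-subtracted mid-body bend-angle series is scanned for sign
    changes; a crossing only counts once the series leaves the +/-
    hysteresis band on the other side, suppressing noise-induced
    crossings. One thrash = two crossings; frequency = thrashes / valid
    duration. The flag is True when the estimate sits so close to the
    fps/2 sampling limit (>= 75% of it) that aliasing may corrupt it.

    By default the hysteresis band adapts to the series: 30% of its robust
    SD (1.4826 MAD), clipped to [0.02, 0.05] rad. The chord-based bend
    angle of a fast-thrashing worm has an amplitude of only ~0.1 rad, which
    a fixed 0.05 rad band would half-count, while the 0.02 rad floor stays
    above centerline-estimation jitter so a static worm reads 0 Hz.
    """
    idx = np.nonzero(kin.valid)[0]
    if len(idx) < 2 or (len(idx) - 1) / kin.fps < 1.0:
        return None, False
    series = kin.bend_rad[idx]
    series = series - series.mean()
    if hysteresis_rad is None:
        robust_sd = 1.4826 * float(np.median(np.abs(series - np.median(series))))
        hysteresis_rad = float(
            np.clip(0.3 * robust_sd, BEND_HYSTERESIS_MIN_RAD, BEND_HYSTERESIS_MAX_RAD)
        )
    times = idx / kin.fps
    state = 0
    crossings = 0
    cross_times: list[float] = []
    last_armed = 0  # index of last sample outside the band
    for i, v in enumerate(series):
        if v > hysteresis_rad:
            if state == -1:
                crossings += 1
                cross_times.append(_cross_time(times, series, last_armed, i))
            state = 1
            last_armed = i
        elif v < -hysteresis_rad:
            if state == 1:
                crossings += 1
                cross_times.append(_cross_time(times, series, last_armed, i))
            state = -1
            last_armed = i
    duration = times[-1] - times[0]
    if len(cross_times) >= 3:
        # period from interpolated crossing instants: immune to the
        # half-period truncation at the clip edges
        freq = (len(cross_times) - 1) / (2.0 * (cross_times[-1] - cross_times[0]))
    else:
        freq = (crossings / 2.0) / duration
    unreliable = freq >= 0.75 * (kin.fps / 2.0)
    return float(freq), bool(unreliable)


def _cross_time(times: np.ndarray, series: np.ndarray, i: int, j: int) -> float:
    """Linear-interpolated zero-crossing instant between samples i and j."""
    vi, vj = series[i], series[j]
    if vi == vj:
        return float(0.5 * (times[i] + times[j]))
    frac = vi / (vi - vj)
    return float(times[i] + frac * (times[j] - times[i]))


def head_tail_amplitude(
    kin: ClipKinematics,
) -> tuple[float | None, float | None, float | None, float | None]:
    """(head_path, tail_path, head_excursion, tail_excursion) in µm.

    Paths are cumulative tip travel over consecutive valid frames
    (primary, the "total movement" reading); excursions are the maximum
    distance of the tip from its mean position (secondary)."""
    idx = np.nonzero(kin.valid)[0]
    if len(idx) < 2:
        return None, None, None, None
    head = kin.tip_track("head")[idx]
    tail = kin.tip_track("tail")[idx]

    def path(track):
        return float(np.sum(np.linalg.norm(np.diff(track, axis=0), axis=1)))

    def excursion(track):
        return float(np.max(np.linalg.norm(track - track.mean(axis=0), axis=1)))

    return path(head), path(tail), excursion(head), excursion(tail)


def responsiveness(kin: ClipKinematics, length_um: float) -> bool:
    """Covered-area criterion: the convex hull of all valid-frame
    centerline points must exceed the area of a circle of radius one body
    length (pi L^2)."""
    pts = np.vstack(
        [kin.centerlines[i].points_um for i in np.nonzero(kin.valid)[0]]
    )
    try:
        hull_area = float(ConvexHull(pts).volume)  # 2-D: volume is area
    except QhullError:
        hull_area = 0.0
    return hull_area > np.pi * length_um ** 2


def phenotype_clip(
    kin: ClipKinematics,
    masks: list[WormMask],
    meta: ClipMeta,
    min_frames: int = MIN_FRAMES_DEFAULT,
) -> PhenotypeRecord:
    """Assemble the full PhenotypeRecord for one clip."""
    rec = PhenotypeRecord(
        worm_id=meta.worm_id,
        condition_mol=meta.condition_mol,
        time_h=meta.time_h,
        n_valid_frames=int(kin.valid.sum()),
    )
    if rec.n_valid_frames < min_frames:
        rec.qc.too_few_frames = True
        rec.qc.notes.append(f"only {rec.n_valid_frames} valid frames")
        return rec
    rec.length_um, rec.area_um2 = length_area(kin, masks, min_frames)
    rec.central_velocity_um_s = central_velocity(kin)
    freq, unreliable = beating_frequency(kin)
    rec.beating_freq_hz = freq
    rec.qc.freq_unreliable = unreliable
    (
        rec.head_amplitude_um,
        rec.tail_amplitude_um,
        rec.head_excursion_um,
        rec.tail_excursion_um,
    ) = head_tail_amplitude(kin)
    rec.qc.orientation_unconfident = not kin.orientation_confident
    if rec.length_um is not None:
        rec.responsive = responsiveness(kin, rec.length_um)
    return rec
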