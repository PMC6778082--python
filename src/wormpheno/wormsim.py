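"""Synthetic single-worm chamber videos with exact ground truth.

The real platform images one *C. elegans* worm per microfluidic growth
chamber (brightfield, 10 s clips at 5 fps every 4 h over 0-80 h of
development). This module emulates that acquisition regime with a
low-dimensional kinematic worm: a constant-arclength midline whose local
tangent angle carries a traveling sine wave (the standard thrashing /
undulation model), rasterised as a dark tapered tube on a brighter chamber
background. Because the worm is generated from closed-form kinematics,
every phenotype the analysis pipeline measures (length, area, centroid
velocity, undulation frequency, head/tail path length) has an exact
ground-truth value, emitted alongside each clip.

A dose-response layer (`GrowthDoseModel`, `simulate_experiment`,
`simulate_phenotype_table`) reproduces the statistical design of a
logarithmic-dilution anthelmintic assay: logistic growth in time,
four-parameter-logistic attenuation of growth and motility with
concentration, and worm-level lognormal variability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .video import ClipMeta, VideoClip, write_clip_tiff

TWO_PI = 2.0 * np.pi

# Canonical logarithmic dilution series (mol/L), control first:
# control, 1 nM, 10 nM, 100 nM, 1 uM, 10 uM, 100 uM, 1 mM.
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (
    0.0, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3,
)


@dataclass(frozen=True)
class WormSimParams:
    """Kinematic and imaging parameters for one synthetic clip.

    length_um        body length (µm)
    width_um         maximal body half-width (µm)
    wave_amplitude   peak local bend of the traveling wave (rad)
    wave_freq_hz     undulation frequency (Hz)
    wavelength_frac  body-wave wavelength as a fraction of body length
    speed_um_s       centroid translation speed (µm/s)
    heading_deg      initial heading (deg, 0 = +x)
    amp_head_bias    linear head-to-tail decay of the wave amplitude
                     (0 = uniform; 0.4 means the tail bends 40% less than
                     the head, emulating head-driven swimming)
    px_um            pixel size (µm/px); 1.3 fills a 1280 µm chamber with
                     a ~984 px frame (10x objective)
    fps, duration_s  acquisition regime (default 5 fps for 10 s)
    noise_sd         additive Gaussian intensity noise SD (on [0,1] scale)
    chamber_px       square frame side (px)
    """

    length_um: float = 600.0
    width_um: float = 14.0
    wave_amplitude: float = 0.55
    wave_freq_hz: float = 1.0
    wavelength_frac: float = 0.65
    speed_um_s: float = 30.0
    heading_deg: float = 0.0
    amp_head_bias: float = 0.4
    seed: int = 0
    px_um: float = 1.3
    fps: float = 5.0
    duration_s: float = 10.0
    noise_sd: float = 0.0
    chamber_px: int = 984
    n_points: int = 101
    worm_intensity: float = 0.25
    background_intensity: float = 0.75
    blur_sigma_px: float = 1.0
    taper_frac: float = 0.10
    tip_width_frac: float = 0.25

    def validate(self) -> None:
        if self.length_um <= 0 or self.width_um <= 0:
            raise ValueError("length_um and width_um must be positive")
        if self.fps <= 0 or self.duration_s <= 0 or self.px_um <= 0:
            raise ValueError("fps, duration_s, px_um must be positive")
        if self.wave_amplitude < 0:
            raise ValueError("wave_amplitude must be >= 0")
        if self.wave_amplitude > np.pi:
            raise ValueError(
                "wave_amplitude > pi rad produces a grossly self-intersecting body"
            )
        if not 0 <= self.amp_head_bias < 1:
            raise ValueError("amp_head_bias must be in [0, 1)")
        if self.wavelength_frac <= 0:
            raise ValueError("wavelength_frac must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))


@dataclass
class GroundTruth:
    """Exact per-clip truth emitted next to each rendered clip.

    Coordinates are µm in (x, y) = (column, row) convention, index 0 of a
    centerline is the head. Masks are the noiseless, pre-blur rasters the
    frames were painted from.
    """

    centerlines_um: np.ndarray          # (F, K, 2)
    centroids_um: np.ndarray            # (F, 2) raster centroids
    length_um: float
    area_um2: float                     # median per-frame raster area
    areas_um2: np.ndarray               # (F,)
    centroid_path_um: float
    head_path_um: float
    tail_path_um: float
    wave_freq_hz: float
    masks: np.ndarray | None = None     # (F, H, W) bool

    def to_json_dict(self) -> dict:
        return {
            "centerlines_um": self.centerlines_um.tolist(),
            "centroids_um": self.centroids_um.tolist(),
            "length_um": float(self.length_um),
            "area_um2": float(self.area_um2),
            "areas_um2": self.areas_um2.tolist(),
            "centroid_path_um": float(self.centroid_path_um),
            "head_path_um": float(self.head_path_um),
            "tail_path_um": float(self.tail_path_um),
            "wave_freq_hz": float(self.wave_freq_hz),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            centerlines_um=np.asarray(d["centerlines_um"], dtype=float),
            centroids_um=np.asarray(d["centroids_um"], dtype=float),
            length_um=d["length_um"],
            area_um2=d["area_um2"],
            areas_um2=np.asarray(d["areas_um2"], dtype=float),
            centroid_path_um=d["centroid_path_um"],
            head_path_um=d["head_path_um"],
            tail_path_um=d["tail_path_um"],
            wave_freq_hz=d["wave_freq_hz"],
        )


def make_centerline(
    params: WormSimParams, t: float, phase: float = 0.0
) -> np.ndarray:
    """Midline of the worm at time t as K ordered (x, y) µm points, head first.

    The curve has exactly constant spacing length_um/(K-1) between
    consecutive points: positions are integrated from the tangent-angle
    field theta(s, t) = A(s) sin(2*pi*s/(lambda) - 2*pi*f*t + phase) with
    A(s) decaying linearly head-to-tail by `amp_head_bias`, evaluated at
    segment midpoints. The whole curve is rigidly translated by
    speed_um_s * t along the initial heading.
    """
    params.validate()
    L = params.length_um
    K = params.n_points
    heading = np.deg2rad(params.heading_deg)
    s = np.linspace(0.0, L, K)
    s_mid = 0.5 * (s[:-1] + s[1:])
    amp = params.wave_amplitude * (1.0 - params.amp_head_bias * s_mid / L)
    wavelength = params.wavelength_frac * L
    theta = heading + amp * np.sin(
        TWO_PI * s_mid / wavelength - TWO_PI * params.wave_freq_hz * t + phase
    )
    if theta.size and (theta.max() - theta.min()) > TWO_PI:
        raise ValueError("bend field winds by more than a full turn (self-intersecting)")
    ds = L / (K - 1)
    steps = ds * np.column_stack([np.cos(theta), np.sin(theta)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    # anchor the body centroid, not the head: the whole body oscillates
    # about the mean axis of progression, as in a real swimming worm
    pts = pts - pts.mean(axis=0)
    pts = pts + params.speed_um_s * t * np.array([np.cos(heading), np.sin(heading)])
    return pts


def halfwidth_profile(params: WormSimParams) -> np.ndarray:
    """Half-width (µm) at each of the K centerline nodes.

    Full half-width along the trunk, tapering linearly to
    tip_width_frac * width_um over the terminal taper_frac of arclength.
    """
    K = params.n_points
    s = np.linspace(0.0, 1.0, K)
    ramp = np.clip(np.minimum(s, 1.0 - s) / params.taper_frac, 0.0, 1.0)
    return params.width_um * (
        params.tip_width_frac + (1.0 - params.tip_width_frac) * ramp
    )


def _rasterize_tube(
    points_px: np.ndarray, halfw_px: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Boolean raster of the tapered tube around a centerline (px coords)."""
    tang = np.gradient(points_px, axis=0)
    norm = np.hypot(tang[:, 0], tang[:, 1])
    norm[norm == 0] = 1.0
    tang = tang / norm[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    left = points_px + normal * halfw_px[:, None]
    right = points_px - normal * halfw_px[:, None]
    poly = np.vstack([left, right[::-1]])
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
    mask[rr, cc] = True
    for tip, r in ((points_px[0], halfw_px[0]), (points_px[-1], halfw_px[-1])):
        rr, cc = draw_disk((tip[1], tip[0]), max(r, 0.5), shape=shape)
        mask[rr, cc] = True
    return mask


def empty_chamber_frame(params: WormSimParams) -> np.ndarray:
    """The wormless chamber image: uniform background intensity.

    The platform records each chamber before worm placement; segmentation
    of a worm that barely moves (a chamber-confined adult, or a paralysed
    worm at high dose) needs this reference because temporal background
    estimation requires worm motion.
    """
    return np.full(
        (params.chamber_px, params.chamber_px),
        params.background_intensity,
        dtype=np.float64,
    )


def render_clip(
    params: WormSimParams,
    store_masks: bool = True,
    meta: ClipMeta | None = None,
) -> tuple[VideoClip, GroundTruth]:
    """Rasterize a full clip: dark tapered worm on a bright background.

    Per frame the noiseless tube raster is painted (worm_intensity on
    background_intensity), Gaussian-blurred (blur_sigma_px) inside the
    worm's bounding box, then additive Gaussian noise (noise_sd) is applied
    frame-wide. The worm trajectory is centred in the chamber; a worm whose
    trajectory cannot fit raises ValueError.
    """
    params.validate()
    n = params.n_frames
    if n < 2:
        raise ValueError("clip must have >= 2 frames (fps * duration_s >= 2)")
    times = np.arange(n) / params.fps
    centerlines = np.stack([make_centerline(params, t) for t in times])

    chamber_um = params.chamber_px * params.px_um
    margin = params.width_um + (3.0 * params.blur_sigma_px + 2.0) * params.px_um
    lo = centerlines.reshape(-1, 2).min(axis=0) - margin
    hi = centerlines.reshape(-1, 2).max(axis=0) + margin
    span = hi - lo
    if np.any(span > chamber_um):
        raise ValueError(
            f"worm trajectory ({span} um) does not fit the chamber ({chamber_um} um)"
        )
    offset = (chamber_um - span) / 2.0 - lo
    centerlines = centerlines + offset

    halfw_px = halfwidth_profile(params) / params.px_um
    shape = (params.chamber_px, params.chamber_px)
    rng = np.random.default_rng(params.seed)

    frames = np.empty((n,) + shape, dtype=np.float32)
    masks = np.empty((n,) + shape, dtype=bool)
    centroids = np.empty((n, 2))
    areas = np.empty(n)
    pad = int(np.ceil(4 * params.blur_sigma_px)) + 2
    for i in range(n):
        pts_px = centerlines[i] / params.px_um
        mask = _rasterize_tube(pts_px, halfw_px, shape)
        masks[i] = mask
        areas[i] = mask.sum() * params.px_um ** 2
        cm = ndimage.center_of_mass(mask)
        centroids[i] = (cm[1] * params.px_um, cm[0] * params.px_um)

        img = np.full(shape, params.background_intensity, dtype=np.float64)
        img[mask] = params.worm_intensity
        if params.blur_sigma_px > 0:
            rows, cols = np.nonzero(mask)
            r0 = max(rows.min() - pad, 0)
            r1 = min(rows.max() + pad + 1, shape[0])
            c0 = max(cols.min() - pad, 0)
            c1 = min(cols.max() + pad + 1, shape[1])
            img[r0:r1, c0:c1] = ndimage.gaussian_filter(
                img[r0:r1, c0:c1], params.blur_sigma_px
            )
        if params.noise_sd > 0:
            img = img + rng.normal(0.0, params.noise_sd, size=shape)
        frames[i] = img.astype(np.float32)

    head_path = float(
        np.sum(np.linalg.norm(np.diff(centerlines[:, 0, :], axis=0), axis=1))
    )
    tail_path = float(
        np.sum(np.linalg.norm(np.diff(centerlines[:, -1, :], axis=0), axis=1))
    )
    centroid_path = float(np.sum(np.linalg.norm(np.diff(centroids, axis=0), axis=1)))

    clip = VideoClip(
        frames=frames, fps=params.fps, px_um=params.px_um, meta=meta or ClipMeta()
    )
    truth = GroundTruth(
        centerlines_um=centerlines,
        centroids_um=centroids,
        length_um=params.length_um,
        area_um2=float(np.median(areas)),
        areas_um2=areas,
        centroid_path_um=centroid_path,
        head_path_um=head_path,
        tail_path_um=tail_path,
        wave_freq_hz=params.wave_freq_hz,
        masks=masks if store_masks else None,
    )
    return clip, truth


# ---------------------------------------------------------------------------
# Dose-response experiment layer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthDoseModel:
    """Growth + motility attenuation model behind a simulated experiment.

    Control body length follows a logistic in time,
    L(t) = L0 + (L_max - L0) / (1 + exp(-k (t - t_mid))), and the compound
    scales length by the four-parameter-logistic factor
    g(c) = 1 / (1 + (c / ic50_growth)^hill_growth). With
    attenuate_increment_only=False (default) the whole length is scaled:
    L(t, c) = L(t) g(c), so the mean at c = ic50 is half the control mean.
    With attenuate_increment_only=True only the post-hatch growth is
    scaled: L(t, c) = L0 + (L(t) - L0) g(c) — worms never fall below
    hatchling size, which is the right regime for rendered experiments (a
    25 µm "worm" cannot exist, let alone be imaged) and makes the
    percentage response an affine 4PL with the same IC50 and a nonzero
    bottom plateau (the partial-agonist shape).

    Motility parameters (wave amplitude, undulation frequency, translation
    speed) are scaled by the analogous factor with ic50_motility /
    hill_motility; in the emulated assay motility is the more sensitive
    phenotype (ic50_motility < ic50_growth).
    """

    L_max_um: float = 1100.0
    L0_um: float = 250.0
    t_mid_h: float = 30.0
    k_h: float = 0.12
    ic50_growth: float = 4.6e-5
    hill_growth: float = 1.2
    ic50_motility: float = 5e-6
    hill_motility: float = 1.0
    attenuate_increment_only: bool = False
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS

    def validate(self) -> None:
        if min(self.L_max_um, self.t_mid_h, self.k_h) <= 0:
            raise ValueError("growth parameters must be positive")
        if self.ic50_growth <= 0 or self.ic50_motility <= 0:
            raise ValueError("IC50 values must be positive")
        cs = list(self.concentrations)
        if cs != sorted(cs) or cs[0] != 0.0:
            raise ValueError("concentrations must be ascending with 0 (control) first")

    def dose_factor_growth(self, c: float) -> float:
        return dose_factor(c, self.ic50_growth, self.hill_growth)

    def dose_factor_motility(self, c: float) -> float:
        return dose_factor(c, self.ic50_motility, self.hill_motility)

    def control_length(self, t_h: float) -> float:
        z = 1.0 / (1.0 + np.exp(-self.k_h * (t_h - self.t_mid_h)))
        return self.L0_um + (self.L_max_um - self.L0_um) * z

    def mean_length(self, t_h: float, c: float) -> float:
        g = self.dose_factor_growth(c)
        if self.attenuate_increment_only:
            return self.L0_um + (self.control_length(t_h) - self.L0_um) * g
        return self.control_length(t_h) * g


def dose_factor(c: float, ic50: float, hill: float) -> float:
    """Four-parameter-logistic inhibition factor on [0, 1]; c = 0 -> 1."""
    if c < 0:
        raise ValueError("concentration must be nonnegative")
    if c == 0:
        return 1.0
    return 1.0 / (1.0 + (c / ic50) ** hill)


# Allometry and motility scaling used by both the rendering and the fast
# statistical path. Half-width ~2.3% of length; worms sweep ~30% of a body
# length per second; lateral head excursion ~20% of length per beat.
HALFWIDTH_FRAC = 0.023
SPEED_FRAC_PER_S = 0.30
FREQ_REF_HZ = 1.0
HEAD_AMP_FRAC = 2.0
TAIL_AMP_RATIO = 0.65


def _worm_params_for(
    model: GrowthDoseModel,
    length_um: float,
    c: float,
    seed: int,
    base: WormSimParams,
) -> WormSimParams:
    """Kinematic parameters for one worm of given length under dose c."""
    m = model.dose_factor_motility(c)
    chamber_um = base.chamber_px * base.px_um
    # keep the trajectory inside the chamber: cap translation
    speed = SPEED_FRAC_PER_S * length_um * m
    max_travel = max(0.0, 0.85 * chamber_um - 1.15 * length_um)
    speed = min(speed, max_travel / base.duration_s)
    return WormSimParams(
        length_um=length_um,
        width_um=max(HALFWIDTH_FRAC * length_um, 2.5 * base.px_um),
        wave_amplitude=base.wave_amplitude * m,
        wave_freq_hz=FREQ_REF_HZ * max(m, 0.02),
        wavelength_frac=base.wavelength_frac,
        speed_um_s=speed,
        heading_deg=base.heading_deg,
        amp_head_bias=base.amp_head_bias,
        seed=seed,
        px_um=base.px_um,
        fps=base.fps,
        duration_s=base.duration_s,
        noise_sd=base.noise_sd,
        chamber_px=base.chamber_px,
        n_points=base.n_points,
    )


def simulate_experiment(
    model: GrowthDoseModel,
    n_worms_per_cond: int,
    timepoints_h: list[float],
    seed: int,
    cv: float = 0.10,
    base_params: WormSimParams | None = None,
    outdir: str | Path | None = None,
    store_masks: bool = True,
):
    """Render a full dose-response experiment: one clip per worm x time point.

    Each worm draws a persistent lognormal size factor (CV `cv`); its length
    at each time point is model.mean_length(t, c) times that factor,
    floored at 100 µm so the smallest drugged larvae remain resolvable.
    Returns (clips, truths, manifest DataFrame); when `outdir` is given the
    dataset is also written to disk (TIFF stacks + JSON truth + CSV
    manifest) and the clip lists are still returned.
    """
    model.validate()
    if n_worms_per_cond < 1:
        raise ValueError("n_worms_per_cond must be >= 1")
    if not timepoints_h:
        raise ValueError("timepoints_h must not be empty")
    base = base_params or WormSimParams()
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log(1.0 + cv ** 2))

    clips: list[VideoClip] = []
    truths: list[GroundTruth] = []
    rows = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        (out / "clips").mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(parents=True, exist_ok=True)

    for ci, c in enumerate(model.concentrations):
        for w in range(n_worms_per_cond):
            worm_id = f"c{ci}_w{w}"
            size_factor = float(np.exp(rng.normal(-0.5 * sigma ** 2, sigma)))
            for t in timepoints_h:
                length = max(model.mean_length(t, c) * size_factor, 100.0)
                clip_seed = int(rng.integers(0, 2 ** 31 - 1))
                params = _worm_params_for(model, length, c, clip_seed, base)
                meta = ClipMeta(worm_id=worm_id, condition_mol=c, time_h=t)
                clip, truth = render_clip(params, store_masks=store_masks, meta=meta)
                clips.append(clip)
                truths.append(truth)
                rel = f"clips/{worm_id}_t{t:g}.tif"
                rows.append(
                    {
                        "clip_path": rel,
                        "worm_id": worm_id,
                        "condition_mol": c,
                        "time_h": t,
                    }
                )
                if out is not None:
                    write_clip_tiff(clip, out / rel)
                    with open(out / "truth" / f"{worm_id}_t{t:g}.json", "w") as fh:
                        json.dump(truth.to_json_dict(), fh)
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return clips, truths, manifest


def simulate_phenotype_table(
    model: GrowthDoseModel,
    n_worms_per_cond: int | tuple[int, int],
    timepoints_h: list[float],
    seed: int,
    cv: float = 0.10,
    cv_meas: float = 0.05,
) -> pd.DataFrame:
    """Draw per-clip phenotype records directly from the statistical model.

    This is the rendering-free layer of the generator: the same growth and
    dose-attenuation structure as `simulate_experiment`, but emitting the
    six phenotypes per worm and time point without rasterising any video.
    Worm-level lognormal size/vigour factors (CV `cv`) persist across time
    points; an independent per-measurement lognormal factor (CV `cv_meas`)
    models segmentation and sampling error. `n_worms_per_cond` may be an
    (inclusive) range, in which case each condition draws its own n —
    emulating uneven group sizes of a real chip run.
    """
    model.validate()
    if not timepoints_h:
        raise ValueError("timepoints_h must not be empty")
    rng = np.random.default_rng(seed)
    sig_w = np.sqrt(np.log(1.0 + cv ** 2))
    sig_m = np.sqrt(np.log(1.0 + cv_meas ** 2))

    def lognorm(r, sig, size=None):
        return np.exp(r.normal(-0.5 * sig ** 2, sig, size=size))

    rows = []
    for ci, c in enumerate(model.concentrations):
        if isinstance(n_worms_per_cond, tuple):
            lo, hi = n_worms_per_cond
            n = int(rng.integers(lo, hi + 1))
        else:
            n = int(n_worms_per_cond)
        if n < 1:
            raise ValueError("n_worms_per_cond must be >= 1")
        g = model.dose_factor_growth(c)
        m = model.dose_factor_motility(c)
        for w in range(n):
            size_f = lognorm(rng, sig_w)
            vigour_f = lognorm(rng, sig_w)
            for t in timepoints_h:
                length = model.control_length(t) * g * size_f * lognorm(rng, sig_m)
                halfw = HALFWIDTH_FRAC * length
                area = 2.0 * halfw * length * 0.92  # taper correction
                vel = SPEED_FRAC_PER_S * length * m * vigour_f * lognorm(rng, sig_m)
                freq = FREQ_REF_HZ * m * vigour_f * lognorm(rng, sig_m)
                head = HEAD_AMP_FRAC * length * m * vigour_f * lognorm(rng, sig_m)
                tail = head * TAIL_AMP_RATIO * lognorm(rng, sig_m)
                rows.append(
                    {
                        "worm_id": f"c{ci}_w{w}",
                        "condition_mol": c,
                        "time_h": t,
                        "length_um": length,
                        "area_um2": area,
                        "central_velocity_um_s": vel,
                        "beating_freq_hz": freq,
                        "head_amplitude_um": head,
                        "tail_amplitude_um": tail,
                        "responsive": vel * 10.0 > np.pi * length,
                        "n_valid_frames": 50,
                    }
                )
    return pd.DataFrame(rows)


def simulate_embryo_table(
    hatch_prob: float,
    dead_l1_prob: float,
    mean_dev_h: float,
    sd_dev_h: float,
    n: int,
    seed: int,
    condition: float = 0.0,
) -> pd.DataFrame:
    """Simulate an embryo event table for one condition.

    Hatching is Bernoulli(hatch_prob); twitching-to-hatching development
    times are Normal(mean_dev_h, sd_dev_h) truncated at 0 (resampled);
    death during L1 is Bernoulli(dead_l1_prob) among hatched embryos only.
    Columns: embryo_id, condition_mol, twitch_time_h, hatch_time_h (NaN for
    unhatched), died_as_l1 (False for unhatched).
    """
    if not (0 <= hatch_prob <= 1 and 0 <= dead_l1_prob <= 1):
        raise ValueError("probabilities must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    hatched = rng.random(n) < hatch_prob
    dev = rng.normal(mean_dev_h, sd_dev_h, size=n)
    if sd_dev_h > 0:
        bad = dev <= 0
        while bad.any():
            dev[bad] = rng.normal(mean_dev_h, sd_dev_h, size=int(bad.sum()))
            bad = dev <= 0
    twitch = np.full(n, 2.0)
    hatch_time = np.where(hatched, twitch + dev, np.nan)
    died = np.where(hatched, rng.random(n) < dead_l1_prob, False)
    return pd.DataFrame(
        {
            "embryo_id": [f"e{i}" for i in range(n)],
            "condition_mol": condition,
            "twitch_time_h": twitch,
            "hatch_time_h": hatch_time,
            "died_as_l1": died,
        }
    )
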