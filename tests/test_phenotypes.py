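"""The six per-clip phenotypes and the responsiveness criterion."""

import numpy as np
import pytest

from wormpheno import (
    WormSimParams,
    analyze_clip,
    beating_frequency,
    central_velocity,
    head_tail_amplitude,
    length_area,
    make_centerline,
    orient_clip,
    render_clip,
    responsiveness,
)
from wormpheno.centerline import Centerline, ClipKinematics
from wormpheno.segmentation import WormMask
from wormpheno.wormsim import empty_chamber_frame


def _kin_from_params(params: WormSimParams) -> ClipKinematics:
    """Kinematics straight from the kinematic model (no rendering): fast
    fixture for phenotype arithmetic."""
    times = np.arange(params.n_frames) / params.fps
    cls = [Centerline(points_um=make_centerline(params, t)) for t in times]
    cents = np.array([c.points_um.mean(axis=0) for c in cls])
    return orient_clip(cls, cents, params.fps)


def _static_kin(n_frames: int = 20) -> ClipKinematics:
    pts = np.column_stack([np.linspace(0, 300, 101), np.zeros(101)])
    cls = [Centerline(points_um=pts.copy()) for _ in range(n_frames)]
    cents = np.tile(pts.mean(axis=0), (n_frames, 1))
    return orient_clip(cls, cents, fps=5.0)


class TestLengthArea:
    def test_recovery_from_rendered_clip(self, std_clip, std_record, std_params):
        _clip, truth = std_clip
        assert std_record.length_um == pytest.approx(std_params.length_um, rel=0.03)
        assert std_record.area_um2 == pytest.approx(truth.area_um2, rel=0.10)

    def test_median_robust_to_outlier_mask(self, std_clip):
        from wormpheno import segment_clip
        from wormpheno.centerline import extract_centerline

        clip, _ = std_clip
        seg = segment_clip(clip)
        cls = [extract_centerline(m) for m in seg.masks]
        cents = np.array([m.centroid_um for m in seg.masks])
        kin = orient_clip(cls, cents, clip.fps)
        l0, a0 = length_area(kin, seg.masks)
        # double one mask's area by injecting a fat blob copy
        big = seg.masks[3].mask.copy()
        big |= np.roll(big, 15, axis=0)
        seg.masks[3] = WormMask(mask=big, px_um=clip.px_um)
        l1, a1 = length_area(kin, seg.masks)
        assert a1 == pytest.approx(a0, rel=0.02)
        assert l1 == l0

    def test_absent_when_too_few_frames(self):
        kin = _static_kin(4)
        l, a = length_area(kin, [None] * 4, min_frames=10)
        assert l is None and a is None


class TestCentralVelocity:
    def test_pure_translation_speed_recovered(self):
        p = WormSimParams(length_um=400.0, width_um=9.2, wave_amplitude=0.0,
                          wave_freq_hz=0.0, speed_um_s=50.0, chamber_px=760,
                          seed=11)
        clip, truth = render_clip(p)
        rec = analyze_clip(clip, background=empty_chamber_frame(p))
        assert rec.central_velocity_um_s == pytest.approx(50.0, abs=2.0)

    def test_static_worm_zero(self):
        kin = _static_kin()
        assert central_velocity(kin) == 0.0

    def test_undulation_in_place_small_centroid_motion(self):
        p = WormSimParams(length_um=400.0, width_um=9.2, speed_um_s=0.0,
                          wave_freq_hz=1.0, wave_amplitude=0.55,
                          chamber_px=512, seed=13)
        clip, truth = render_clip(p)
        rec = analyze_clip(clip)
        head_rate = rec.head_amplitude_um / (clip.duration_s - 1 / clip.fps)
        assert rec.central_velocity_um_s < 0.10 * head_rate

    def test_gap_bridging_divides_by_actual_time(self):
        kin = _static_kin(20)
        # move centroid linearly but knock out middle frames
        kin.centroids_um[:, 0] = np.arange(20) * 10.0
        kin.valid[5:10] = False
        kin.centroids_um[5:10] = np.nan
        v = central_velocity(kin)
        assert v == pytest.approx(10.0 * 5.0)  # 10 um/frame at 5 fps


class TestBeatingFrequency:
    def test_one_hz_recovered(self, std_record):
        assert std_record.beating_freq_hz == pytest.approx(1.0, abs=0.1)

    def test_static_worm_zero_hz(self):
        kin = _static_kin()
        freq, unreliable = beating_frequency(kin)
        assert freq == 0.0
        assert not unreliable

    def test_nyquist_guard_flags_fast_wave(self):
        p = WormSimParams(length_um=400.0, width_um=9.2, speed_um_s=10.0,
                          wave_freq_hz=3.0, wave_amplitude=0.4,
                          chamber_px=512, seed=17)
        kin = _kin_from_params(p)
        freq, unreliable = beating_frequency(kin)
        assert unreliable  # 3 Hz at 5 fps is beyond fps/2

    def test_short_series_absent(self):
        kin = _static_kin(3)
        freq, _ = beating_frequency(kin)
        assert freq is None


class TestHeadTailAmplitude:
    def test_static_worm_zero(self):
        kin = _static_kin()
        head, tail, he, te = head_tail_amplitude(kin)
        assert head == 0.0 and tail == 0.0

    def test_rendered_paths_match_truth(self, std_clip, std_record):
        _clip, truth = std_clip
        assert std_record.head_amplitude_um == pytest.approx(
            truth.head_path_um, rel=0.10
        )
        assert std_record.tail_amplitude_um == pytest.approx(
            truth.tail_path_um, rel=0.10
        )

    def test_head_exceeds_tail_with_head_biased_wave(self):
        p = WormSimParams(length_um=500.0, width_um=11.5, amp_head_bias=0.5,
                          speed_um_s=20.0, chamber_px=512, seed=19)
        kin = _kin_from_params(p)
        head, tail, _, _ = head_tail_amplitude(kin)
        assert head > tail

    def test_excursion_not_larger_than_path(self, std_record):
        assert std_record.head_excursion_um <= std_record.head_amplitude_um


class TestResponsiveness:
    @staticmethod
    def _meander_kin(length: float = 100.0, travel: float = 800.0,
                     lateral: float = 100.0, n: int = 30):
        """Worm sweeping a band: advancing in x while meandering +/-
        `lateral` in y, so the hull is roughly travel x lateral."""
        body = np.column_stack([np.linspace(0, length, 101), np.zeros(101)])
        cls, cents = [], []
        for i in range(n):
            off = np.array([travel * i / (n - 1),
                            lateral * np.sin(2 * np.pi * i / 8)])
            pts = body + off
            cls.append(Centerline(points_um=pts))
            cents.append(pts.mean(axis=0))
        return orient_clip(cls, np.array(cents), fps=5.0)

    def test_static_worm_not_responsive(self):
        kin = _static_kin()
        assert not responsiveness(kin, 300.0)

    def test_long_meandering_travel_responsive(self):
        # covered band ~ travel x L with travel > pi*L => hull > pi L^2
        kin = self._meander_kin(length=100.0, travel=800.0, lateral=100.0)
        assert responsiveness(kin, 100.0)

    def test_scale_invariance(self):
        kin = self._meander_kin(length=100.0, travel=800.0, lateral=100.0)
        verdict = responsiveness(kin, 100.0)
        scaled = ClipKinematics(
            centerlines=[
                Centerline(points_um=2.0 * c.points_um) if c else None
                for c in kin.centerlines
            ],
            centroids_um=2.0 * kin.centroids_um,
            bend_rad=kin.bend_rad,
            valid=kin.valid,
            fps=kin.fps,
        )
        assert responsiveness(scaled, 200.0) == verdict


class TestRecordAssembly:
    def test_absent_not_zero_on_clip_failure(self):
        from wormpheno import VideoClip

        frames = np.full((12, 64, 64), 0.75)
        clip = VideoClip(frames=frames, fps=5.0, px_um=1.3)
        rec = analyze_clip(clip)
        assert rec.qc.clip_failed
        assert rec.length_um is None
        assert rec.central_velocity_um_s is None
        assert rec.responsive is None

    def test_intensity_offset_invariance(self, std_clip, std_record):
        clip, _ = std_clip
        from wormpheno import VideoClip

        shifted = VideoClip(frames=clip.frames + 0.05, fps=clip.fps,
                            px_um=clip.px_um, meta=clip.meta)
        rec = analyze_clip(shifted)
        assert rec.length_um == pytest.approx(std_record.length_um, rel=0.01)
        assert rec.central_velocity_um_s == pytest.approx(
            std_record.central_velocity_um_s, rel=0.02
        )
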