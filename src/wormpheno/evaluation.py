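"""Benchmark suites: recovery of simulator ground truth by the pipeline.

Each routine renders (or draws) synthetic data with known truth, runs the
analysis exactly as a user would, and reports recovery statistics. The
tests and the reproduction script both call these with their own problem
sizes; all randomness is derived from an explicit seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .doseresponse import (
    FitConfig,
    embryo_stats,
    fit_ic50,
    fourpl_response,
    percent_response,
    time_averaged_index,
)
from .pipeline import analyze_clip
from .segmentation import segment_clip
from .video import ClipMeta
from .wormsim import (
    DEFAULT_CONCENTRATIONS,
    GrowthDoseModel,
    WormSimParams,
    empty_chamber_frame,
    render_clip,
    simulate_embryo_table,
    simulate_phenotype_table,
)


def _clip_draw(rng: np.random.Generator, chamber_px: int = 760,
               length_range=(250.0, 620.0), noise_sd: float = 0.0,
               n_frames: int = 50) -> WormSimParams:
    """One random moving-worm clip parameter draw for the benchmark suites."""
    length = float(rng.uniform(*length_range))
    chamber_um = chamber_px * 1.3
    speed_cap = max(10.0, (0.88 * chamber_um - 1.25 * length) / (n_frames / 5.0))
    return WormSimParams(
        length_um=length,
        width_um=max(0.023 * length, 3.5),
        wave_freq_hz=float(rng.uniform(0.5, 2.0)),
        wave_amplitude=float(rng.uniform(0.3, 0.65)),
        speed_um_s=min(float(rng.uniform(15.0, 60.0)), speed_cap),
        heading_deg=float(rng.uniform(0.0, 360.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
        noise_sd=noise_sd,
        chamber_px=chamber_px,
        duration_s=n_frames / 5.0,
    )


def segmentation_iou_suite(
    n_clips: int = 20, n_frames: int = 50, seed: int = 0
) -> dict:
    """Mean per-frame IoU of segmentation vs ground-truth rasters on
    noiseless moving-worm clips."""
    rng = np.random.default_rng(seed)
    per_clip = []
    for _ in range(n_clips):
        params = _clip_draw(rng, n_frames=n_frames)
        clip, truth = render_clip(params)
        seg = segment_clip(clip)
        ious = []
        for wm, gt in zip(seg.masks, truth.masks):
            union = (wm.mask | gt).sum()
            ious.append((wm.mask & gt).sum() / union if union else 0.0)
        per_clip.append(float(np.mean(ious)))
    return {"mean_iou": float(np.mean(per_clip)), "per_clip_iou": per_clip}


def morphometry_suite(
    lengths_um=(150.0, 250.0, 400.0, 600.0, 800.0, 1000.0, 1100.0),
    seed: int = 0,
    n_frames: int = 30,
) -> dict:
    """Relative centerline-length and area errors across body sizes.

    Large worms barely translate in a chamber, so the wormless reference
    background is supplied (as the platform records it before loading).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for L in lengths_um:
        params = WormSimParams(
            length_um=float(L),
            width_um=max(0.023 * L, 3.5),
            speed_um_s=min(15.0, max(0.0, (1130.0 - L)) / (n_frames / 5.0)),
            wave_freq_hz=1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
            chamber_px=984,
            duration_s=n_frames / 5.0,
        )
        clip, truth = render_clip(params)
        rec = analyze_clip(clip, background=empty_chamber_frame(params))
        rows.append(
            {
                "length_um": float(L),
                "len_err": rec.length_um / truth.length_um - 1.0,
                "area_err": rec.area_um2 / truth.area_um2 - 1.0,
            }
        )
    df = pd.DataFrame(rows)
    return {
        "max_abs_len_err": float(df["len_err"].abs().max()),
        "max_abs_area_err": float(df["area_err"].abs().max()),
        "table": df,
    }


def motility_suite(n_clips: int = 12, seed: int = 0, n_frames: int = 50) -> dict:
    """Velocity, beating-frequency, head/tail-path recovery on moving worms."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_clips):
        params = _clip_draw(rng, chamber_px=984, length_range=(300.0, 700.0),
                            n_frames=n_frames)
        clip, truth = render_clip(params)
        rec = analyze_clip(clip)
        if rec.central_velocity_um_s is None:
            continue
        v_true = truth.centroid_path_um / ((params.n_frames - 1) / params.fps)
        rows.append(
            {
                "vel_err": rec.central_velocity_um_s / v_true - 1.0,
                "freq_err_hz": rec.beating_freq_hz - truth.wave_freq_hz,
                "head_err": rec.head_amplitude_um / truth.head_path_um - 1.0,
                "tail_err": rec.tail_amplitude_um / truth.tail_path_um - 1.0,
            }
        )
    df = pd.DataFrame(rows)
    return {
        "n_analyzed": len(df),
        "max_abs_vel_err": float(df["vel_err"].abs().max()),
        "max_abs_freq_err_hz": float(df["freq_err_hz"].abs().max()),
        "max_abs_head_err": float(df["head_err"].abs().max()),
        "max_abs_tail_err": float(df["tail_err"].abs().max()),
        "median_abs_vel_err": float(df["vel_err"].abs().median()),
        "median_abs_freq_err_hz": float(df["freq_err_hz"].abs().median()),
        "median_abs_head_err": float(df["head_err"].abs().median()),
        "median_abs_tail_err": float(df["tail_err"].abs().median()),
        "table": df,
    }


def ic50_selfconsistency(
    top: float = 100.0, bottom: float = 0.0, hill: float = 1.0,
    ic50: float = 1e-5,
) -> dict:
    """Noiseless 4PL samples at the 7 tested concentrations -> fit must
    reproduce all four parameters to numerical precision."""
    concs = np.array(DEFAULT_CONCENTRATIONS[1:])
    resp = pd.DataFrame(
        {
            "condition_mol": concs,
            "percent": fourpl_response(concs, top, bottom, hill, ic50),
        }
    )
    fit = fit_ic50(resp, FitConfig(weighted=False))
    return {
        "verdict": fit.verdict,
        "rel_err_ic50": abs(fit.ic50 / ic50 - 1.0),
        "abs_err_top": abs(fit.top - top),
        "abs_err_bottom": abs(fit.bottom - bottom),
        "abs_err_hill": abs(fit.hill - hill),
        "r2": fit.r2,
    }


def ic50_recovery_study(
    n_experiments: int = 200,
    seed: int = 0,
    model: GrowthDoseModel | None = None,
) -> dict:
    """IC50 recovery at realistic group sizes (5-12 worms per condition).

    Each experiment draws phenotype records from the statistical layer of
    the generator (growth + motility dose attenuation with worm-level
    lognormal variability), runs percent-response normalisation, and fits
    the 4PL. Reports the median |log10(IC50_est / IC50_true)| for the
    length phenotype and how often the motility-before-growth IC50
    ordering of the simulation truth survives estimation.
    """
    model = model or GrowthDoseModel()
    rng = np.random.default_rng(seed)
    dlog = []
    n_order_ok = 0
    n_order_total = 0
    for _ in range(n_experiments):
        s = int(rng.integers(0, 2**31 - 1))
        tab = simulate_phenotype_table(
            model, (5, 12), [24.0, 36.0, 48.0, 60.0, 72.0], seed=s
        )
        fit_len = fit_ic50(
            percent_response(tab, "length_um", 48.0), phenotype="length_um"
        )
        _, fit_vel = time_averaged_index(tab, "central_velocity_um_s")
        if fit_len.ok:
            dlog.append(abs(np.log10(fit_len.ic50 / model.ic50_growth)))
        if fit_len.ok and fit_vel.ok:
            n_order_total += 1
            if fit_vel.ic50 < fit_len.ic50:
                n_order_ok += 1
    return {
        "n_ok": len(dlog),
        "median_abs_dlog10": float(np.median(dlog)),
        "ordering_rate": n_order_ok / max(n_order_total, 1),
        "n_order_total": n_order_total,
    }


def refusal_study(n_runs: int = 100, seed: int = 0, sd_percent: float = 8.0) -> dict:
    """Flat (null) percentage responses must be refused (verdict no_ic50)."""
    concs = np.array(DEFAULT_CONCENTRATIONS[1:])
    rng = np.random.default_rng(seed)
    n_refused = 0
    for _ in range(n_runs):
        resp = pd.DataFrame(
            {
                "condition_mol": concs,
                "percent": 100.0 + rng.normal(0.0, sd_percent, concs.size),
                "percent_sem": np.full(concs.size, sd_percent),
            }
        )
        n_refused += fit_ic50(resp).verdict == "no_ic50"
    return {"refusal_rate": n_refused / n_runs}


def embryo_study(
    seed: int = 0,
    n_embryos: int = 10000,
    hatch_prob: float = 0.70,
    n_null_sims: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Hatch-fraction recovery at large n, and one-way ANOVA type-I error
    under the null (three identical conditions)."""
    tab = simulate_embryo_table(hatch_prob, 0.10, 9.0, 1.0, n_embryos, seed=seed)
    hatch_frac = float(tab["hatch_time_h"].notna().mean())
    rng = np.random.default_rng(seed + 1)
    n_reject = 0
    for _ in range(n_null_sims):
        tabs = [
            simulate_embryo_table(
                0.8, 0.1, 9.0, 1.0, 40,
                seed=int(rng.integers(0, 2**31 - 1)), condition=c,
            )
            for c in (0.0, 1e-6, 1e-4)
        ]
        _, _, p = embryo_stats(pd.concat(tabs, ignore_index=True))
        n_reject += p < alpha
    return {"hatch_fraction": hatch_frac, "anova_type1_rate": n_reject / n_null_sims}


def end_to_end_video_ic50(
    seed: int = 0,
    n_worms: int = 4,
    time_h: float = 36.0,
    model: GrowthDoseModel | None = None,
) -> dict:
    """Full video pipeline dose-response recovery at one time point.

    Renders one clip per worm per concentration on a dense dilution grid,
    runs segment -> centerline -> phenotypes, normalises length by control
    and fits the 4PL. Geometry is scaled so every stage fits one chamber:
    adult control length 650 µm in a 988 µm frame.
    """
    model = model or GrowthDoseModel(
        L_max_um=650.0, L0_um=200.0, t_mid_h=18.0, k_h=0.12,
        ic50_growth=4.6e-5, hill_growth=1.2,
        ic50_motility=5e-6, hill_motility=1.0,
        attenuate_increment_only=True,
        concentrations=(
            0.0, 1e-9, 1e-8, 1e-7, 1e-6, 3.2e-6, 1e-5, 3.2e-5, 1e-4, 3.2e-4, 1e-3,
        ),
    )
    rng = np.random.default_rng(seed)
    base = WormSimParams(chamber_px=760, noise_sd=0.02)
    bg = empty_chamber_frame(base)
    sigma = np.sqrt(np.log(1.0 + 0.10**2))
    rows = []
    from .wormsim import _worm_params_for

    for ci, c in enumerate(model.concentrations):
        for w in range(n_worms):
            size_f = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
            length = max(model.mean_length(time_h, c) * size_f, 120.0)
            params = _worm_params_for(
                model, length, c, int(rng.integers(0, 2**31 - 1)), base
            )
            clip, _ = render_clip(
                params, store_masks=False,
                meta=ClipMeta(f"c{ci}_w{w}", c, time_h),
            )
            rec = analyze_clip(clip, background=bg)
            rows.append(rec.to_dict())
    records = pd.DataFrame(rows)
    resp = percent_response(records, "length_um", time_h)
    fit = fit_ic50(resp, phenotype="length_um", time_label=f"{time_h:g}h")
    out = {
        "verdict": fit.verdict,
        "ic50_true": model.ic50_growth,
        "ic50_est": fit.ic50,
        "records": records,
    }
    if fit.ok:
        out["rel_err"] = abs(fit.ic50 / model.ic50_growth - 1.0)
    return out
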