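"""Control-normalised dose-response analysis: percentage-response tables,
four-parameter-logistic (4PL) "partial agonist" fits with IC50 and an
explicit refusal verdict, time-averaged indices, logistic growth-curve
fits, and embryo-stage statistics.

Responses are expressed as percent of the mean control (c = 0) value at
the same time point; the control anchors the top of the curve and is
excluded from the log-dose axis. The 4PL form is

    R(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill)

with the bottom plateau free ("partial agonist": a nonzero residual
response at saturating dose). Fits are weighted nonlinear least squares
on log10(c) with multistart initialisation; a fit that does not pin down
the IC50 (non-convergence, IC50 outside the tested range, wide
log10(IC50) standard error, or poor R^2) returns the verdict ``no_ic50``
rather than a number — flat or high-variance responses must refuse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

PHENOTYPE_COLUMNS = [
    "length_um",
    "area_um2",
    "central_velocity_um_s",
    "beating_freq_hz",
    "head_amplitude_um",
    "tail_amplitude_um",
]


# ---------------------------------------------------------------------------
# Percentage response
# ---------------------------------------------------------------------------

def percent_response(
    records: pd.DataFrame, phenotype: str, time_h: float
) -> pd.DataFrame:
    """Per-condition mean, SEM and percent-of-control at one time point.

    Absent values are excluded, never zero-filled. Raises ValueError when
    no control (condition_mol == 0) worms exist at `time_h`.
    Columns: condition_mol, time_h, phenotype, n, mean, sem, percent,
    percent_sem.
    """
    df = records[np.isclose(records["time_h"], time_h)]
    df = df[np.isfinite(df[phenotype].astype(float))]
    if df.empty or not (df["condition_mol"] == 0).any():
        raise ValueError(f"no control data at time {time_h} h")
    rows = []
    control_mean = df.loc[df["condition_mol"] == 0, phenotype].mean()
    if control_mean <= 0:
        raise ValueError("control mean must be positive for normalisation")
    for c, grp in df.groupby("condition_mol"):
        vals = grp[phenotype].astype(float).to_numpy()
        n = len(vals)
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(
            {
                "condition_mol": float(c),
                "time_h": time_h,
                "phenotype": phenotype,
                "n": n,
                "mean": mean,
                "sem": sem,
                "percent": 100.0 * mean / control_mean,
                "percent_sem": 100.0 * sem / control_mean if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("condition_mol").reset_index(drop=True)


# ---------------------------------------------------------------------------
# 4PL model and IC50 fitting
# ---------------------------------------------------------------------------

def fourpl_response(
    c: float | np.ndarray, top: float, bottom: float, hill: float, ic50: float
) -> float | np.ndarray:
    """4PL percentage response; c = 0 returns the control limit `top`."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentrations must be nonnegative")
    with np.errstate(divide="ignore"):
        out = bottom + (top - bottom) / (1.0 + (c_arr / ic50) ** hill)
    out = np.where(c_arr == 0, top, out)
    return float(out) if np.isscalar(c) else out


@dataclass
class FitConfig:
    weighted: bool = True
    sem_floor: float = 1.0          # percent points; floor on SEM weights
    max_se_log_ic50: float = 0.5    # SE of log10(IC50), in decades
    min_r2: float = 0.3
    range_slack: float = 10.0       # IC50 must lie in [cmin/slack, cmax*slack]
    min_effect_rms: float = 4.0     # (top-bottom) must exceed this x residual RMS


@dataclass
class DoseResponseFit:
    phenotype: str
    time_label: str
    top: float | None = None
    bottom: float | None = None
    hill: float | None = None
    ic50: float | None = None
    r2: float | None = None
    se_log10_ic50: float | None = None
    ci_ic50: tuple[float, float] | None = None
    verdict: str = "no_ic50"
    reason: str = ""

    @property
    def ok(self) -> bool:
        return self.verdict == "ok"

    def to_dict(self) -> dict:
        d = {
            "phenotype": self.phenotype,
            "time": self.time_label,
            "model": "4PL partial agonist (free bottom), log10-dose abscissa",
            "top": self.top,
            "bottom": self.bottom,
            "hill": self.hill,
            "ic50_mol": self.ic50,
            "r2": self.r2,
            "se_log10_ic50": self.se_log10_ic50,
            "ci_ic50_mol": list(self.ci_ic50) if self.ci_ic50 else None,
            "verdict": self.verdict,
            "reason": self.reason,
        }
        return d


def _fourpl_log(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    top, bottom, hill, logic50 = p
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - logic50)))


def fit_ic50(
    resp: pd.DataFrame,
    config: FitConfig | None = None,
    phenotype: str | None = None,
    time_label: str | None = None,
) -> DoseResponseFit:
    """Fit the 4PL to a percent-response slice and judge reliability.

    `resp` needs columns condition_mol and percent (percent_sem used for
    weights when present). The control row (c = 0) anchors normalisation
    but is excluded from the log-dose fit. At least 4 distinct non-control
    concentrations are required.

    Multistart: log10(IC50) on a grid spanning the tested range +/- one
    decade, bottom from {0, min response}, hill from {0.5, 1, 2}, top from
    the lowest-dose response; the best start is polished to tight
    tolerances. The verdict is ``no_ic50`` when the optimiser fails, the
    IC50 leaves [cmin/10, cmax*10], the standard error of log10(IC50)
    exceeds 0.5 decades, the fitted drop (top - bottom) stays within the
    residual noise, or R^2 < 0.3.
    """
    cfg = config or FitConfig()
    fit = DoseResponseFit(
        phenotype=phenotype or (resp["phenotype"].iloc[0] if "phenotype" in resp else ""),
        time_label=time_label
        or (str(resp["time_h"].iloc[0]) if "time_h" in resp else ""),
    )
    d = resp[resp["condition_mol"] > 0]
    d = d[np.isfinite(d["percent"].astype(float))]
    conc = d["condition_mol"].to_numpy(dtype=float)
    if len(np.unique(conc)) < 4:
        raise ValueError("need >= 4 distinct non-control concentrations")
    y = d["percent"].to_numpy(dtype=float)
    x = np.log10(conc)

    if cfg.weighted and "percent_sem" in d and np.isfinite(d["percent_sem"]).all():
        sem = np.maximum(d["percent_sem"].to_numpy(dtype=float), cfg.sem_floor)
        w = 1.0 / sem
    else:
        w = np.ones_like(y)

    def residuals(p):
        return w * (_fourpl_log(x, p) - y)

    lo = np.array([0.0, -50.0, 0.05, x.min() - 2.0])
    hi = np.array([400.0, 300.0, 10.0, x.max() + 2.0])
    y_top0 = y[np.argmin(x)]
    starts = []
    for logic50 in np.linspace(x.min() - 1.0, x.max() + 1.0, 5):
        for bottom0 in (0.0, float(y.min())):
            for hill0 in (0.7, 1.5):
                starts.append(np.array([max(y_top0, 1.0), bottom0, hill0, logic50]))

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(
                residuals, p0, bounds=(lo, hi), method="trf", max_nfev=120
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        fit.reason = "optimizer failed to converge from every start"
        return fit
    # polish to tight tolerances for oracle-grade self-consistency
    try:
        best = least_squares(
            residuals, best.x, bounds=(lo, hi), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
    except Exception:
        pass

    top, bottom, hill, logic50 = best.x
    yhat = _fourpl_log(x, best.x)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    dof = max(len(y) - 4, 1)
    s2 = 2.0 * best.cost / dof
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * s2
        se_logic50 = float(np.sqrt(max(cov[3, 3], 0.0)))
    except np.linalg.LinAlgError:
        se_logic50 = np.inf

    fit.top = float(top)
    fit.bottom = float(bottom)
    fit.hill = float(hill)
    fit.ic50 = float(10.0 ** logic50)
    fit.r2 = float(r2)
    fit.se_log10_ic50 = se_logic50
    fit.ci_ic50 = (
        float(10.0 ** np.clip(logic50 - 1.96 * se_logic50, -300, 300)),
        float(10.0 ** np.clip(logic50 + 1.96 * se_logic50, -300, 300)),
    )

    cmin, cmax = conc.min(), conc.max()
    resid_rms = float(np.sqrt(np.mean((y - yhat) ** 2)))
    if not (cmin / cfg.range_slack <= fit.ic50 <= cmax * cfg.range_slack):
        fit.reason = f"fitted IC50 {fit.ic50:.3g} outside the tested range"
    elif se_logic50 > cfg.max_se_log_ic50:
        fit.reason = f"log10(IC50) SE {se_logic50:.2f} decades too wide"
    elif (top - bottom) < cfg.min_effect_rms * resid_rms:
        fit.reason = (
            f"dose effect {top - bottom:.1f}% within noise "
            f"({cfg.min_effect_rms} x residual RMS {resid_rms:.1f}%)"
        )
    elif r2 < cfg.min_r2:
        fit.reason = f"R^2 {r2:.2f} below {cfg.min_r2}"
    else:
        fit.verdict = "ok"
    return fit


# ---------------------------------------------------------------------------
# Time-averaged indices
# ---------------------------------------------------------------------------

def time_averaged_index(
    records: pd.DataFrame,
    phenotype: str,
    config: FitConfig | None = None,
) -> tuple[pd.DataFrame, DoseResponseFit]:
    """Time-averaged dose-response: per worm, mean over its time points;
    per condition, mean/SEM of worm means normalised by control; 4PL fit.

    A worm missing some time points still contributes the mean of its
    available values. Requires >= 2 distinct time points overall.
    """
    df = records[np.isfinite(records[phenotype].astype(float))]
    if df["time_h"].nunique() < 2:
        raise ValueError("time-averaged index needs >= 2 time points")
    worm_means = (
        df.groupby(["condition_mol", "worm_id"])[phenotype].mean().reset_index()
    )
    if not (worm_means["condition_mol"] == 0).any():
        raise ValueError("no control worms")
    control_mean = worm_means.loc[
        worm_means["condition_mol"] == 0, phenotype
    ].mean()
    rows = []
    for c, grp in worm_means.groupby("condition_mol"):
        vals = grp[phenotype].to_numpy(dtype=float)
        n = len(vals)
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(
            {
                "condition_mol": float(c),
                "time_h": np.nan,
                "phenotype": phenotype,
                "n": n,
                "mean": mean,
                "sem": sem,
                "percent": 100.0 * mean / control_mean,
                "percent_sem": 100.0 * sem / control_mean if n > 1 else np.nan,
            }
        )
    table = pd.DataFrame(rows).sort_values("condition_mol").reset_index(drop=True)
    fit = fit_ic50(
        table, config=config, phenotype=phenotype, time_label="time-averaged"
    )
    return table, fit


# ---------------------------------------------------------------------------
# Growth curves (logistic in time)
# ---------------------------------------------------------------------------

@dataclass
class GrowthFit:
    condition_mol: float
    phenotype: str
    plateau: float | None = None
    midpoint_h: float | None = None
    rate_h: float | None = None
    r2: float | None = None
    converged: bool = False
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "condition_mol": self.condition_mol,
            "phenotype": self.phenotype,
            "model": "logistic in time: plateau / (1 + exp(-rate (t - midpoint)))",
            "plateau": self.plateau,
            "midpoint_h": self.midpoint_h,
            "rate_per_h": self.rate_h,
            "r2": self.r2,
            "converged": self.converged,
            "reason": self.reason,
        }


def fit_growth_curve(
    records: pd.DataFrame, condition_mol: float, phenotype: str
) -> GrowthFit:
    """Least-squares logistic-in-time fit of one condition's mean phenotype.

    value(t) = plateau / (1 + exp(-rate (t - midpoint))). Needs >= 5 time
    points; a degenerate (flat) series is reported as non-converged with
    parameters absent rather than a spurious plateau.
    """
    out = GrowthFit(condition_mol=condition_mol, phenotype=phenotype)
    df = records[
        np.isclose(records["condition_mol"], condition_mol)
        & np.isfinite(records[phenotype].astype(float))
    ]
    series = df.groupby("time_h")[phenotype].mean()
    if len(series) < 5:
        raise ValueError("growth fit needs >= 5 time points")
    t = series.index.to_numpy(dtype=float)
    y = series.to_numpy(dtype=float)

    if np.ptp(y) < 1e-9 * max(abs(y).max(), 1.0):
        out.reason = "constant series: rate indeterminate"
        return out

    def residuals(p):
        plateau, mid, rate = p
        return plateau / (1.0 + np.exp(-rate * (t - mid))) - y

    lo = np.array([1e-9, t.min() - 100.0, 1e-4])
    hi = np.array([10.0 * max(y.max(), 1.0), t.max() + 100.0, 10.0])
    best = None
    for rate0 in (0.05, 0.1, 0.3):
        for mid0 in (np.median(t), t.min() + 0.25 * np.ptp(t)):
            p0 = np.clip(
                np.array([max(y.max(), 1.0), mid0, rate0]), lo + 1e-12, hi - 1e-12
            )
            try:
                res = least_squares(residuals, p0, bounds=(lo, hi), method="trf")
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        out.reason = "optimizer failed"
        return out
    best = least_squares(
        residuals, best.x, bounds=(lo, hi), method="trf",
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    plateau, mid, rate = best.x
    yhat = plateau / (1.0 + np.exp(-rate * (t - mid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    if rate <= 2e-4 or r2 < 0.0:
        out.reason = "degenerate fit (rate collapsed)"
        return out
    out.plateau = float(plateau)
    out.midpoint_h = float(mid)
    out.rate_h = float(rate)
    out.r2 = float(r2)
    out.converged = True
    return out


def plateau_ratio(
    records: pd.DataFrame, condition_mol: float, phenotype: str
) -> float:
    """Fitted plateau of one condition relative to the control plateau —
    the "drop of the maximum length/area" style summary."""
    f_c = fit_growth_curve(records, condition_mol, phenotype)
    f_0 = fit_growth_curve(records, 0.0, phenotype)
    if not (f_c.converged and f_0.converged):
        raise ValueError("growth fits did not converge")
    return f_c.plateau / f_0.plateau


# ---------------------------------------------------------------------------
# Embryo-stage statistics
# ---------------------------------------------------------------------------

def embryo_stats(table: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Per-condition embryo summaries and one-way ANOVA on development time.

    Input columns: condition_mol, twitch_time_h, hatch_time_h (NaN when
    unhatched), died_as_l1. Per condition: mean +/- SEM twitching-to-
    hatching time (hatched embryos only; SEM absent when n < 2), hatch
    fraction, dead-L1 fraction among hatched. The classical one-way ANOVA
    F and p are computed across conditions with >= 2 hatched embryos.
    """
    rows = []
    groups = []
    for c, grp in table.groupby("condition_mol"):
        hatched = grp[np.isfinite(grp["hatch_time_h"])]
        dev = (hatched["hatch_time_h"] - hatched["twitch_time_h"]).to_numpy(float)
        n_h = len(hatched)
        rows.append(
            {
                "condition_mol": float(c),
                "n_embryos": len(grp),
                "n_hatched": n_h,
                "hatch_fraction": n_h / len(grp),
                "dead_l1_fraction": (
                    float(hatched["died_as_l1"].mean()) if n_h else np.nan
                ),
                "dev_time_mean_h": float(dev.mean()) if n_h else np.nan,
                "dev_time_sem_h": (
                    float(dev.std(ddof=1) / np.sqrt(n_h)) if n_h > 1 else np.nan
                ),
            }
        )
        if n_h >= 2:
            groups.append(dev)
    if len(groups) >= 2:
        f_stat, p_val = stats.f_oneway(*groups)
    else:
        raise ValueError("ANOVA needs >= 2 conditions with >= 2 hatched embryos")
    summary = pd.DataFrame(rows).sort_values("condition_mol").reset_index(drop=True)
    return summary, float(f_stat), float(p_val)
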