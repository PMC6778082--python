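"""Dose-response analysis: normalisation, 4PL fits, refusals, growth fits,
embryo statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormpheno import (
    FitConfig,
    GrowthDoseModel,
    embryo_stats,
    fit_growth_curve,
    fit_ic50,
    fourpl_response,
    percent_response,
    plateau_ratio,
    simulate_embryo_table,
    simulate_phenotype_table,
    time_averaged_index,
)
from wormpheno.wormsim import DEFAULT_CONCENTRATIONS

CONCS = np.array(DEFAULT_CONCENTRATIONS[1:])


def _records(values_by_cond: dict, time_h: float = 36.0,
             phenotype: str = "length_um") -> pd.DataFrame:
    rows = []
    for c, vals in values_by_cond.items():
        for i, v in enumerate(vals):
            rows.append({"worm_id": f"c{c}_w{i}", "condition_mol": c,
                         "time_h": time_h, phenotype: v})
    return pd.DataFrame(rows)


class TestPercentResponse:
    def test_control_is_100_with_sem(self):
        df = _records({0.0: [90, 100, 110], 1e-6: [50, 55, 45]})
        tab = percent_response(df, "length_um", 36.0)
        ctrl = tab[tab["condition_mol"] == 0].iloc[0]
        assert ctrl["percent"] == pytest.approx(100.0)
        assert ctrl["percent_sem"] > 0

    def test_half_control_is_50(self):
        df = _records({0.0: [100, 100], 1e-6: [50, 50]})
        tab = percent_response(df, "length_um", 36.0)
        assert tab.loc[tab["condition_mol"] == 1e-6, "percent"].iloc[0] == 50.0

    def test_missing_control_errors(self):
        df = _records({1e-6: [50, 50]})
        with pytest.raises(ValueError, match="control"):
            percent_response(df, "length_um", 36.0)

    def test_absent_values_excluded_not_zeroed(self):
        df = _records({0.0: [100, 100], 1e-6: [50, np.nan]})
        tab = percent_response(df, "length_um", 36.0)
        row = tab[tab["condition_mol"] == 1e-6].iloc[0]
        assert row["n"] == 1
        assert row["percent"] == 50.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        df = _records({0.0: [100.0, 120.0], 1e-6: [60.0, 70.0]})
        base = percent_response(df, "length_um", 36.0)["percent"].to_numpy()
        df2 = df.copy()
        df2["length_um"] = df2["length_um"] * scale
        scaled = percent_response(df2, "length_um", 36.0)["percent"].to_numpy()
        assert np.allclose(base, scaled, rtol=1e-9)


class TestFourPL:
    def test_half_maximal_at_ic50(self):
        assert fourpl_response(1e-5, 100, 0, 1.3, 1e-5) == pytest.approx(50.0)
        assert fourpl_response(2e-6, 80, 20, 2.0, 2e-6) == pytest.approx(50.0)

    def test_asymptotes(self):
        assert fourpl_response(0.0, 100, 5, 1, 1e-6) == 100.0
        assert fourpl_response(1e3, 100, 5, 1, 1e-6) == pytest.approx(5.0, abs=1e-3)

    def test_tenth_of_ic50_closed_form(self):
        # hill 1: response at ic50/10 is 100/(1 + 0.1) = 90.909...%
        assert fourpl_response(4.6e-6, 100, 0, 1, 4.6e-5) == pytest.approx(
            100.0 / 1.1
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            fourpl_response(-1e-6, 100, 0, 1, 1e-5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        hill=st.floats(min_value=0.3, max_value=4.0),
        ic50=st.floats(min_value=1e-8, max_value=1e-4),
    )
    def test_monotone_decreasing_for_positive_hill(self, hill, ic50):
        # non-increasing everywhere (steep curves saturate to the top
        # plateau at machine precision), strictly lower at saturating dose
        c = np.geomspace(1e-9, 1e-3, 40)
        y = fourpl_response(c, 100.0, 0.0, hill, ic50)
        assert np.all(np.diff(y) <= 0)
        assert y[-1] < y[0]


class TestFitIC50:
    @pytest.mark.parametrize(
        "top,bottom,hill,ic50",
        [
            (100.0, 0.0, 1.0, 1e-5),
            (100.0, 30.0, 1.5, 4.6e-5),   # partial agonist
            (110.0, 10.0, 0.7, 2e-7),
        ],
    )
    def test_noiseless_selfconsistency_machine_precision(
        self, top, bottom, hill, ic50
    ):
        resp = pd.DataFrame(
            {"condition_mol": CONCS,
             "percent": fourpl_response(CONCS, top, bottom, hill, ic50)}
        )
        fit = fit_ic50(resp, FitConfig(weighted=False))
        assert fit.verdict == "ok"
        assert fit.ic50 == pytest.approx(ic50, rel=1e-6)
        assert fit.top == pytest.approx(top, abs=1e-6)
        assert fit.bottom == pytest.approx(bottom, abs=1e-6)
        assert fit.hill == pytest.approx(hill, rel=1e-6)
        assert fit.r2 > 0.999

    def test_flat_response_refused(self):
        resp = pd.DataFrame(
            {"condition_mol": CONCS, "percent": np.full(CONCS.size, 100.0)}
        )
        fit = fit_ic50(resp)
        assert fit.verdict == "no_ic50"

    def test_too_few_concentrations_error(self):
        resp = pd.DataFrame(
            {"condition_mol": [1e-9, 1e-8, 1e-7], "percent": [100, 80, 20]}
        )
        with pytest.raises(ValueError, match="4 distinct"):
            fit_ic50(resp)

    def test_out_of_range_ic50_refused(self):
        # barely-declining curve whose midpoint sits far above the range
        y = fourpl_response(CONCS, 100, 0, 1, 5e-1)
        fit = fit_ic50(pd.DataFrame({"condition_mol": CONCS, "percent": y}))
        assert fit.verdict == "no_ic50"


class TestTimeAveragedIndex:
    def test_time_constant_matches_single_timepoint(self):
        model = GrowthDoseModel(k_h=1e-6)  # essentially flat in time
        tab = simulate_phenotype_table(model, 8, [24.0, 48.0], seed=0,
                                       cv=0.0, cv_meas=0.0)
        avg_tab, _ = time_averaged_index(tab, "length_um")
        single = percent_response(tab, "length_um", 24.0)
        assert np.allclose(
            avg_tab["percent"].to_numpy(), single["percent"].to_numpy(),
            rtol=1e-9,
        )

    def test_worm_with_missing_timepoint_still_counts(self):
        conds = {0.0: [100.0, 100.0], 1e-8: [95.0, 96.0], 1e-7: [80.0, 82.0],
                 1e-6: [50.0, 52.0], 1e-5: [20.0, 22.0]}
        df = pd.concat(
            [
                _records(conds, time_h=24.0),
                _records(conds, time_h=48.0),
            ],
            ignore_index=True,
        )
        # knock out one worm's 48 h value: it still contributes its 24 h mean
        drop = (df["worm_id"] == "1e-06_w0") & (df["time_h"] == 48.0)
        df.loc[drop, "length_um"] = np.nan
        tab, _fit = time_averaged_index(df, "length_um")
        row = tab[tab["condition_mol"] == 1e-6].iloc[0]
        assert row["n"] == 2
        assert row["percent"] == pytest.approx(51.0, abs=1.0)

    def test_requires_two_timepoints(self):
        df = _records({0.0: [100], 1e-6: [50]})
        with pytest.raises(ValueError, match="2 time points"):
            time_averaged_index(df, "length_um")

    def test_motility_before_growth_ordering(self):
        model = GrowthDoseModel()  # ic50_motility << ic50_growth
        tab = simulate_phenotype_table(model, 10, [24.0, 48.0, 72.0], seed=9)
        _, f_vel = time_averaged_index(tab, "central_velocity_um_s")
        _, f_len = time_averaged_index(tab, "length_um")
        assert f_vel.ok and f_len.ok
        assert f_vel.ic50 < f_len.ic50


class TestGrowthCurve:
    @staticmethod
    def _logistic_records(plateau, mid, rate, cond=0.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for t in np.arange(4.0, 80.0, 8.0):
            val = plateau / (1.0 + np.exp(-rate * (t - mid)))
            for w in range(3):
                rows.append(
                    {"worm_id": f"{cond}_w{w}", "condition_mol": cond,
                     "time_h": t,
                     "length_um": val * (1 + rng.normal(0, noise))}
                )
        return pd.DataFrame(rows)

    def test_noiseless_exact_recovery(self):
        df = self._logistic_records(900.0, 30.0, 0.15)
        fit = fit_growth_curve(df, 0.0, "length_um")
        assert fit.converged
        assert fit.plateau == pytest.approx(900.0, rel=1e-6)
        assert fit.midpoint_h == pytest.approx(30.0, rel=1e-6)
        assert fit.rate_h == pytest.approx(0.15, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_plateau_ratio_recovers_max_length_drop(self):
        df = pd.concat(
            [
                self._logistic_records(900.0, 30.0, 0.15, cond=0.0,
                                       noise=0.02, seed=1),
                self._logistic_records(900.0 * 0.28, 30.0, 0.15, cond=1e-3,
                                       noise=0.02, seed=2),
            ]
        )
        ratio = plateau_ratio(df, 1e-3, "length_um")
        assert ratio == pytest.approx(0.28, abs=0.05)

    def test_constant_series_flagged(self):
        rows = [
            {"worm_id": "w", "condition_mol": 0.0, "time_h": t,
             "length_um": 500.0}
            for t in np.arange(0.0, 48.0, 8.0)
        ]
        fit = fit_growth_curve(pd.DataFrame(rows), 0.0, "length_um")
        assert not fit.converged
        assert fit.plateau is None

    def test_too_few_timepoints_error(self):
        df = self._logistic_records(900.0, 30.0, 0.15)
        df = df[df["time_h"] < 30.0]
        with pytest.raises(ValueError, match="5 time points"):
            fit_growth_curve(df, 0.0, "length_um")


class TestEmbryoStats:
    def test_per_condition_summary(self):
        tabs = pd.concat(
            [
                simulate_embryo_table(0.7, 0.1, 9.0, 1.0, 400, seed=i,
                                      condition=c)
                for i, c in enumerate([0.0, 1e-6, 1e-4])
            ],
            ignore_index=True,
        )
        summary, f_stat, p = embryo_stats(tabs)
        assert len(summary) == 3
        assert summary["hatch_fraction"].between(0.6, 0.8).all()
        assert summary["dev_time_mean_h"].sub(9.0).abs().max() < 0.5
        assert 0.0 <= p <= 1.0

    def test_single_hatched_embryo_sem_absent(self):
        rows = [
            {"condition_mol": 0.0, "twitch_time_h": 2.0, "hatch_time_h": 11.0,
             "died_as_l1": False},
            {"condition_mol": 0.0, "twitch_time_h": 2.0, "hatch_time_h": 10.0,
             "died_as_l1": False},
            {"condition_mol": 1e-6, "twitch_time_h": 2.0, "hatch_time_h": 11.0,
             "died_as_l1": False},
            {"condition_mol": 1e-6, "twitch_time_h": 2.0,
             "hatch_time_h": np.nan, "died_as_l1": False},
            {"condition_mol": 1e-4, "twitch_time_h": 2.0, "hatch_time_h": 12.0,
             "died_as_l1": False},
            {"condition_mol": 1e-4, "twitch_time_h": 2.0, "hatch_time_h": 10.0,
             "died_as_l1": True},
        ]
        summary, _, _ = embryo_stats(pd.DataFrame(rows))
        one = summary[summary["condition_mol"] == 1e-6].iloc[0]
        assert np.isnan(one["dev_time_sem_h"])
        assert one["dev_time_mean_h"] == 9.0

    def test_anova_needs_two_groups(self):
        tab = simulate_embryo_table(0.9, 0.0, 9.0, 1.0, 50, seed=0)
        with pytest.raises(ValueError, match="ANOVA"):
            embryo_stats(tab)
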