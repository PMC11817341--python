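"""Parameter estimation: lumped-capacitance h_T fit, Biot/resistance
checks, (D, h_m) grid search, isotherm refit and fit statistics."""

import numpy as np
import pandas as pd
import pytest

import shrimpdry as sd
from shrimpdry.estimation import (
    GridSpec,
    LumpedBodySpec,
    biot_number,
    evaluate_grid_objective,
    fit_heat_transfer_coefficient,
    fit_isotherm,
    goodness_of_fit,
    grid_search_D_hm,
    lumped_temperature,
    resistance_check,
    simulate_grid,
)
from shrimpdry.properties import SorptionIsotherm

BODY = LumpedBodySpec()
T_AIR, T0 = 333.15, 298.15


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        r2, rmse = goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r2 == 1.0 and rmse == 0.0

    def test_hand_computed_example(self):
        r2, rmse = goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert rmse == pytest.approx(np.sqrt(1.0 / 3.0))
        assert r2 == pytest.approx(0.5)

    def test_mean_predictor_gives_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        r2, _ = goodness_of_fit(obs, np.full(4, obs.mean()))
        assert r2 == pytest.approx(0.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="variance"):
            r2, rmse = goodness_of_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(r2) and rmse > 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1.0], [1.0])


class TestLumpedCapacitance:
    @pytest.mark.parametrize("h_true", [57.0, 62.9])
    def test_noiseless_recovery(self, h_true):
        t = np.arange(0.0, 1800.0, 30.0)
        T = lumped_temperature(t, h_true, BODY, T_AIR, T0)
        fit = fit_heat_transfer_coefficient(t, T, BODY, T_AIR, T0=T0)
        assert fit.h_T == pytest.approx(h_true, rel=1e-3)
        assert fit.r_squared > 0.999999

    def test_noisy_monte_carlo_recovery(self):
        # 20 replicates at sigma=0.3 K recover the truth within 2 % on avg
        t = np.arange(0.0, 10800.0, 30.0)
        T = lumped_temperature(t, 57.0, BODY, T_AIR, T0)
        rng = np.random.default_rng(42)
        fits = [
            fit_heat_transfer_coefficient(
                t, T + rng.normal(0, 0.3, t.shape), BODY, T_AIR, T0=T0).h_T
            for _ in range(20)
        ]
        assert np.mean(fits) == pytest.approx(57.0, rel=0.02)

    def test_scale_invariance_of_identified_group(self):
        # only h_T A/(m c_p) is identified: scaling m c_p and the true
        # h_T by the same factor leaves the curve (hence tau) unchanged
        t = np.arange(0.0, 1800.0, 30.0)
        T = lumped_temperature(t, 57.0, BODY, T_AIR, T0)
        big = LumpedBodySpec(mass=BODY.mass * 2, surface_area=BODY.surface_area,
                             volume=BODY.volume, heat_capacity=BODY.heat_capacity,
                             conductivity=BODY.conductivity)
        fit = fit_heat_transfer_coefficient(t, T, big, T_AIR, T0=T0)
        assert fit.h_T == pytest.approx(114.0, rel=1e-3)
        assert fit.tau == pytest.approx(
            BODY.mass * BODY.heat_capacity / (57.0 * BODY.surface_area), rel=1e-3)

    def test_flat_series_warns(self):
        t = np.arange(0.0, 300.0, 30.0)
        with pytest.warns(UserWarning, match="poorly conditioned"):
            fit = fit_heat_transfer_coefficient(
                t, np.full(t.shape, T0 + 1e-6), BODY, T_AIR, T0=T0)
        assert fit.quality_warning

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_heat_transfer_coefficient([0, 30, 60], [298, 299, 300],
                                          BODY, T_AIR)


class TestBiotAndResistances:
    def test_biot_below_lumped_threshold(self):
        # both measured coefficients keep the aluminum body lumped
        assert biot_number(62.9, BODY) <= 6.5e-4
        assert biot_number(57.0, BODY) < 6.5e-4
        assert biot_number(62.9, BODY) == pytest.approx(6.37e-4, rel=1e-2)

    def test_zero_h(self):
        assert biot_number(0.0, BODY) == 0.0

    def test_tray_resistances(self):
        chk = resistance_check(BODY, 57.0)
        assert chk.R_cond == pytest.approx(2.2e-6, rel=0.01)
        assert chk.R_conv == pytest.approx(0.018, rel=0.03)
        assert chk.R_cond / chk.R_conv == pytest.approx(1.2e-4, rel=0.05)
        assert chk.tray_negligible


@pytest.fixture(scope="module")
def recovery_setup(cyl_mesh_4mm):
    """Truth curve and simulated sub-grid around the truth cell, on a
    coarse mesh with enlarged steps (identical discretization for truth
    and candidates, so recovery is exact by construction)."""
    cfg = sd.baseline_config(60, max_time_step=30.0, output_interval=300.0)
    grid = GridSpec(D_values=(5.5e-10, 6.0e-10, 6.5e-10, 7.0e-10, 7.5e-10),
                    h_m_values=(0.007, 0.008, 0.009))
    curves = simulate_grid(cyl_mesh_4mm, cfg, grid)
    truth = curves[(6.5e-10, 0.008)]
    t_obs = np.asarray([15, 30, 45, 60, 90, 120, 150, 180], dtype=float) * 60
    data = pd.DataFrame({
        "time_s": t_obs,
        "Xdb_avg": np.interp(t_obs, truth.times, truth.Xdb_avg),
        "T_probe_C": np.interp(t_obs, truth.times, truth.T_probe) - 273.15,
    })
    return cfg, grid, curves, data


class TestGridSearch:
    def test_default_grid_is_printed_screening_grid(self):
        g = GridSpec()
        assert len(g.D_values) == 11 and len(g.h_m_values) == 6
        assert g.D_values[0] == pytest.approx(5e-10)
        assert g.D_values[-1] == pytest.approx(1e-9)
        assert g.h_m_values == (0.005, 0.006, 0.007, 0.008, 0.009, 0.01)

    def test_noiseless_self_recovery(self, cyl_mesh_4mm, recovery_setup):
        cfg, grid, curves, data = recovery_setup
        res = grid_search_D_hm(data, cyl_mesh_4mm, cfg, grid=grid,
                               grid_curves=curves)
        assert res.parameters["D"]["value"] == pytest.approx(6.5e-10)
        assert res.parameters["h_m"]["value"] == pytest.approx(0.008)
        assert len(res.table) == 15
        assert res.objective == res.table["objective"].min()

    def test_off_grid_truth_lands_on_neighbor(self, cyl_mesh_4mm, recovery_setup):
        cfg, grid, curves, _ = recovery_setup
        from dataclasses import replace
        off = sd.simulate(cyl_mesh_4mm, replace(cfg, D=7.2e-10)).curve
        t_obs = np.asarray([15, 30, 60, 90, 120, 150, 180], dtype=float) * 60
        data = pd.DataFrame({
            "time_s": t_obs,
            "Xdb_avg": np.interp(t_obs, off.times, off.Xdb_avg),
            "T_probe_C": np.interp(t_obs, off.times, off.T_probe) - 273.15,
        })
        res = grid_search_D_hm(data, cyl_mesh_4mm, cfg, grid=grid,
                               grid_curves=curves)
        assert res.parameters["D"]["value"] in (7.0e-10, 7.5e-10)

    def test_single_cell_grid(self, cyl_mesh_4mm, recovery_setup):
        cfg, _, curves, data = recovery_setup
        g1 = GridSpec(D_values=(6.0e-10,), h_m_values=(0.009,))
        res = grid_search_D_hm(data, cyl_mesh_4mm, cfg, grid=g1,
                               grid_curves={k: v for k, v in curves.items()
                                            if k == (6.0e-10, 0.009)})
        assert res.parameters["D"]["value"] == pytest.approx(6.0e-10)
        assert len(res.table) == 1

    def test_resampling_invariance(self, cyl_mesh_4mm, recovery_setup):
        cfg, grid, curves, data = recovery_setup
        t_fine = np.arange(900.0, 10800.0 + 1, 450.0)
        truth = curves[(6.5e-10, 0.008)]
        fine = pd.DataFrame({
            "time_s": t_fine,
            "Xdb_avg": np.interp(t_fine, truth.times, truth.Xdb_avg),
            "T_probe_C": np.interp(t_fine, truth.times, truth.T_probe) - 273.15,
        })
        r1 = grid_search_D_hm(data, cyl_mesh_4mm, cfg, grid=grid,
                              grid_curves=curves)
        r2 = grid_search_D_hm(fine, cyl_mesh_4mm, cfg, grid=grid,
                              grid_curves=curves)
        assert r1.parameters == r2.parameters

    def test_temperature_only_mode(self, cyl_mesh_4mm, recovery_setup):
        cfg, grid, curves, data = recovery_setup
        res = grid_search_D_hm(data, cyl_mesh_4mm, cfg, grid=grid, mode="temperature",
                               grid_curves=curves)
        assert np.isnan(res.table["rmse_X"]).all()

    def test_failed_candidate_gets_infinite_objective(self, recovery_setup):
        cfg, grid, curves, data = recovery_setup
        broken = dict(curves)
        broken[(5.5e-10, 0.007)] = None
        table = evaluate_grid_objective(broken, data)
        row = table[(table.D == 5.5e-10) & (table.h_m == 0.007)]
        assert np.isinf(row["objective"]).all()


class TestIsothermFit:
    @pytest.mark.parametrize("label,params", [
        (60, (6.03, 11.00, 0.0980)),
        (70, (11.09, 11.54, 0.7195)),
    ])
    def test_noiseless_recovery_of_fitted_parameters(self, label, params):
        iso = SorptionIsotherm.for_air_temperature(label)
        # sample where the sigmoid actually varies (log-spaced moisture)
        X = np.geomspace(1e-4, 2.0, 40)
        aw = iso.water_activity(X)
        keep = (aw > 1e-3) & (aw < 1 - 1e-6)
        fit = fit_isotherm(X[keep], aw[keep],
                           initial_guess=(8.0, 10.0, 0.5),
                           air_temperature_label=label)
        assert fit.A == pytest.approx(params[0], rel=0.01)
        assert fit.B == pytest.approx(params[1], rel=0.01)
        assert fit.C == pytest.approx(params[2], rel=0.01)

    def test_noisy_monte_carlo_recovery(self):
        # sigma = 0.02 on a_w over 20 replicates: the pooled median
        # parameter error stays below 10 %.  The identifiability study
        # uses the clean-sigmoid nesting: under the default correlation
        # the monotone floor leaves A only weakly constrained by noisy
        # data (its effect is confined to the flat low-moisture branch).
        iso = SorptionIsotherm.for_air_temperature(70, nesting="exp-inside")
        X = np.geomspace(0.005, 2.0, 60)
        aw = iso.water_activity(X)
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(20):
            noisy = np.clip(aw + rng.normal(0, 0.02, aw.shape), 1e-4, 1 - 1e-4)
            fit = fit_isotherm(X, noisy, initial_guess=(10.0, 10.0, 0.6),
                               nesting="exp-inside")
            errs += [abs(fit.A / 11.09 - 1), abs(fit.B / 11.54 - 1),
                     abs(fit.C / 0.7195 - 1)]
        assert np.median(errs) < 0.10

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_isotherm([0.1, 0.2, 0.3], [0.2, 0.4, 0.6])  # too few
        with pytest.raises(ValueError):
            fit_isotherm([0.1, 0.2, 0.3, 0.4], [0.2, 0.4, 0.6, 1.0])
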