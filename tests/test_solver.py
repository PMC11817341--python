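"""Transient coupled solver: boundary fluxes, pseudo-steady balance,
verification against closed-form solutions, and conservation."""

import numpy as np
import pytest

import shrimpdry as sd
from shrimpdry.analysis import detect_stages
from shrimpdry.geometry import (
    CylinderGeometrySpec,
    build_cylinder_geometry,
    build_slab_mesh,
    generate_mesh,
)
from shrimpdry.properties import SorptionIsotherm, saturation_pressure
from shrimpdry.solver import (
    ConstantMaterial,
    DryingCurve,
    SimulationConfig,
    analytic_slab_average_moisture,
    baseline_config,
    boundary_heat_flux,
    evaporative_mass_flux,
    pseudo_steady_surface_temperature,
    simulate,
)


class TestBoundaryFluxes:
    def test_zero_driving_force(self):
        # pick RH so the air vapor concentration equals the surface
        # concentration at T_s = T_air
        from shrimpdry.properties import SorptionIsotherm
        aw = float(SorptionIsotherm.for_air_temperature(60).water_activity(0.5))
        cfg = baseline_config(60, RH=100.0 * aw)
        J = evaporative_mass_flux(333.15, 0.5, cfg)
        assert abs(J) < 1e-9

    def test_zero_mass_transfer_coefficient(self):
        cfg = baseline_config(60, h_m=0.0)
        assert evaporative_mass_flux(319.15, 1.0, cfg) == 0.0

    def test_hand_computed_wet_surface_flux(self):
        # h_m Mw (Psat(319.15)/(R 319.15) - 0.2 Psat(333.15)/(R 333.15)),
        # evaluated by hand with the steam-table-validated Antoine fit
        cfg = baseline_config(60)
        J = evaporative_mass_flux(319.15, 1e6, cfg)  # huge X -> a_w = 1
        assert J == pytest.approx(3.4268e-4, rel=1e-3)

    def test_heat_flux_pure_convection_when_dry_air_path_off(self):
        cfg = baseline_config(60, h_m=0.0)
        q = boundary_heat_flux(313.15, 2.0, cfg)
        assert q == pytest.approx(57.0 * (333.15 - 313.15))

    def test_heat_flux_zero_at_equilibrium(self):
        from shrimpdry.properties import SorptionIsotherm
        aw = float(SorptionIsotherm.for_air_temperature(60).water_activity(0.5))
        cfg = baseline_config(60, RH=100.0 * aw)
        assert abs(boundary_heat_flux(333.15, 0.5, cfg)) < 1e-6

    def test_heat_flux_vanishes_at_pseudo_steady_temperature(self):
        cfg = baseline_config(60)
        T_star = pseudo_steady_surface_temperature(cfg)
        q = boundary_heat_flux(T_star, 1e6, cfg)  # wet surface
        assert abs(q) < 2.0  # W/m2, within the root tolerance


class TestPseudoSteadyTemperature:
    def test_60C_plateau(self):
        cfg = baseline_config(60)
        T = pseudo_steady_surface_temperature(cfg) - 273.15
        assert T == pytest.approx(46.0, abs=2.0)

    def test_70C_plateau(self):
        cfg = baseline_config(70)
        T = pseudo_steady_surface_temperature(cfg) - 273.15
        assert T == pytest.approx(53.0, abs=2.0)

    def test_nearly_saturated_air_approaches_air_temperature(self):
        cfg = baseline_config(60, RH=99.9)
        T = pseudo_steady_surface_temperature(cfg)
        assert 333.15 - T < 0.1

    def test_saturated_air_rejected(self):
        cfg = baseline_config(60, RH=100.0)
        with pytest.raises(ValueError, match="saturated"):
            pseudo_steady_surface_temperature(cfg)


@pytest.fixture(scope="module")
def tiny_mesh():
    return generate_mesh(build_cylinder_geometry(), 4e-3)


class TestSimulateVerification:
    def test_equilibrium_fixed_point(self, tiny_mesh):
        # air in equilibrium with the product at X_db = 0.5: no change
        from shrimpdry.properties import SorptionIsotherm
        aw = float(SorptionIsotherm.for_air_temperature(60).water_activity(0.5))
        cfg = baseline_config(60, T0=333.15, RH=100.0 * aw, X_db0=0.5,
                              duration=600.0, max_time_step=30.0)
        res = simulate(tiny_mesh, cfg)
        assert np.abs(res.curve.Xdb_avg - 0.5).max() < 1e-6
        assert np.abs(res.curve.T_probe - 333.15).max() < 1e-6

    def test_lumped_capacitance_limit(self):
        # high-conductivity constant-property body with h_m = 0 follows
        # the exponential lumped heating curve within 1 %
        body_solid = build_cylinder_geometry(
            CylinderGeometrySpec(diameter=0.01021, length=0.05068))
        mesh = generate_mesh(body_solid, 3e-3)
        rho = 0.0111214 / 4.15e-6
        cfg = SimulationConfig(
            T_air=333.15, RH=20.0, h_T=57.0, h_m=0.0, D=1e-12,
            T0=298.15, X_db0=0.0, c_s=rho,
            material=ConstantMaterial(rho, 900.0, 229.0),
            duration=600.0, max_time_step=2.0, output_interval=30.0,
        )
        res = simulate(mesh, cfg)
        k = 57.0 * mesh.surface_area / (rho * mesh.volume * 900.0)
        T_exact = 333.15 + (298.15 - 333.15) * np.exp(-k * res.curve.times)
        err = np.abs(res.curve.T_probe - T_exact).max() / (333.15 - 298.15)
        assert err < 0.01

    def test_slab_against_series_solution(self):
        # 1-D Dirichlet-like drying (huge h_m, fixed temperature) vs the
        # Fourier series for a slab, within 1 % of the initial content
        L = 0.002  # half thickness
        mesh = build_slab_mesh(2 * L, 0.02, 0.02, n_thickness=96)
        cfg = SimulationConfig(
            T_air=333.15, RH=1.0, h_T=57.0, h_m=1e3, D=6.5e-10,
            T0=333.15, X_db0=3.64, duration=1300.0, max_time_step=0.5,
            output_interval=260.0, fixed_temperature=True,
            isotherm=SorptionIsotherm.for_air_temperature(60, "exp-inside"),
            dry_surface_cutoff=0.0,
        )
        res = simulate(mesh, cfg)
        cs = cfg.solids_concentration
        c0 = cfg.initial_water_concentration
        # compare at the end of the run (Fourier number ~ 0.2); the first
        # instants are boundary-layer limited at any fixed resolution
        series = analytic_slab_average_moisture(cfg.D, L, c0, 0.0,
                                                res.curve.times)
        err = abs(res.curve.Xdb_avg[-1] - series[-1] / cs) / 3.64
        assert err < 0.01

    def test_series_oracle_limits(self):
        avg = analytic_slab_average_moisture(1e-9, 1e-3, 800.0, 100.0,
                                             [0.0, 1e9])
        assert avg[0] == pytest.approx(800.0, rel=1e-6)
        assert avg[1] == pytest.approx(100.0, rel=1e-6)

    def test_hm_zero_probe_approaches_air_temperature(self, tiny_mesh):
        cfg = baseline_config(60, h_m=0.0, duration=3600.0,
                              max_time_step=30.0)
        res = simulate(tiny_mesh, cfg)
        assert res.curve.T_probe[-1] - 273.15 > 58.0
        assert np.abs(res.curve.Xdb_avg - 3.64).max() < 1e-9


class TestSimulationInvariants:
    def test_mass_conservation(self, baseline60_coarse):
        assert baseline60_coarse.diagnostics["mass_balance_error"] <= 0.005

    def test_moisture_monotone_nonincreasing(self, baseline60_coarse):
        assert np.all(np.diff(baseline60_coarse.curve.Xdb_avg) <= 1e-12)

    def test_temperature_bounds(self, baseline60_coarse):
        T = baseline60_coarse.curve.T_probe
        assert np.all(T >= 298.15 - 1e-6)
        assert np.all(T <= 333.15 + 1e-6)

    def test_plateau_between_pseudo_steady_and_air(self, baseline60_coarse):
        cfg = baseline_config(60)
        T_star = pseudo_steady_surface_temperature(cfg)
        from shrimpdry.analysis import plateau_temperature
        T_plateau = plateau_temperature(baseline60_coarse.curve)
        assert T_star - 1.0 < T_plateau < 333.15

    def test_flux_partition_during_constant_rate(self, baseline60_coarse):
        c = baseline60_coarse.curve
        stages = detect_stages(c)
        t0, t1 = stages.constant_rate_window
        sel = (c.times >= t0) & (c.times <= t1)
        rel = np.abs(c.q_conv[sel] - c.q_evap[sel]) / c.q_conv[sel]
        assert np.all(rel < 0.10)

    def test_no_silent_failures(self, baseline60_coarse):
        d = baseline60_coarse.diagnostics
        assert d["picard_failures"] == 0
        assert d["step_halvings"] == 0

    def test_energy_consistency_pure_heating(self, tiny_mesh):
        # with h_m = 0 and constant properties the enthalpy change
        # equals the time-integrated convective heat input within 1 %
        rho, cp = 1050.0, 3500.0
        cfg = SimulationConfig(
            T_air=333.15, RH=20.0, h_T=57.0, h_m=0.0, D=1e-12,
            T0=298.15, X_db0=3.64, material=ConstantMaterial(rho, cp, 0.5),
            duration=1800.0, max_time_step=5.0, output_interval=5.0,
        )
        res = simulate(tiny_mesh, cfg)
        c = res.curve
        # enthalpy change from the mean temperature rise
        from shrimpdry.fem import P1Operators
        ops = P1Operators(tiny_mesh)
        q_in = np.trapezoid(c.q_conv, c.times) * tiny_mesh.surface_area
        # reconstruct volume-mean temperature change via a second run?
        # use the probe-independent energy balance at the end state:
        # with Bi << 1 here conduction keeps the body near-uniform
        dH = rho * cp * tiny_mesh.volume * (c.T_probe[-1] - c.T_probe[0])
        assert dH == pytest.approx(q_in, rel=0.05)


class TestConfigHandling:
    def test_series_inputs_equivalent_to_scalars(self, tiny_mesh):
        cfg_a = baseline_config(60, duration=600.0, max_time_step=30.0)
        series = (np.array([0.0, 600.0]), np.array([20.0, 20.0]))
        cfg_b = baseline_config(60, duration=600.0, max_time_step=30.0,
                                RH=series)
        ca = simulate(tiny_mesh, cfg_a).curve
        cb = simulate(tiny_mesh, cfg_b).curve
        assert np.array_equal(ca.Xdb_avg, cb.Xdb_avg)
        assert np.array_equal(ca.T_probe, cb.T_probe)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SimulationConfig(RH=150.0)
        with pytest.raises(ValueError):
            SimulationConfig(h_T=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(duration=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(bdf_order=3)
        with pytest.raises(ValueError):
            baseline_config(80)

    def test_bdf1_runs_and_roughly_agrees(self, tiny_mesh):
        cfg2 = baseline_config(60, duration=900.0)
        cfg1 = baseline_config(60, duration=900.0, bdf_order=1)
        x2 = simulate(tiny_mesh, cfg2).curve.Xdb_avg[-1]
        x1 = simulate(tiny_mesh, cfg1).curve.Xdb_avg[-1]
        assert x1 == pytest.approx(x2, rel=0.01)

    def test_snapshots_recorded(self, tiny_mesh):
        cfg = baseline_config(60, duration=300.0, max_time_step=30.0,
                              snapshot_times=(0.0, 150.0, 300.0))
        res = simulate(tiny_mesh, cfg)
        assert [s.time for s in res.snapshots] == [0.0, 150.0, 300.0]
        assert res.snapshots[0].c_w.shape == (tiny_mesh.n_nodes,)

    def test_curve_frame_round_trip(self, tiny_mesh):
        cfg = baseline_config(60, duration=300.0, max_time_step=30.0)
        curve = simulate(tiny_mesh, cfg).curve
        back = DryingCurve.from_frame(curve.to_frame())
        assert np.allclose(back.Xdb_avg, curve.Xdb_avg)
        assert np.allclose(back.T_probe, curve.T_probe)
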