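"""Plant submodels and the tank integrator."""

import math

import numpy as np
import pytest

from rhizodose.ions import IONS, N_IONS, nutrient_vector
from rhizodose.model_core import (PlantParams, TankState, integrate,
                                  leaf_area_index, root_length,
                                  root_surface_area, system_derivatives,
                                  transpiration_rate, uptake_rate,
                                  weekly_replacement)

from conftest import ConstantEnvironment


def test_nutrient_vector_validation():
    v = nutrient_vector({ion: 1.0 for ion in IONS})
    assert v.shape == (N_IONS,)
    with pytest.raises(ValueError):
        nutrient_vector([1.0, 2.0])
    with pytest.raises(ValueError):
        nutrient_vector([-1.0] * N_IONS)
    with pytest.raises(ValueError):
        nutrient_vector([np.nan] * N_IONS)


class TestGrowthCurves:
    def test_root_length_origin_and_asymptote(self, toy_params):
        assert root_length(0.0, toy_params) == pytest.approx(1.0 / 10.0)
        assert root_length(1e7, toy_params) == pytest.approx(1.0)

    def test_root_length_midpoint(self, toy_params):
        # K1*exp(-k1 t) = 1 at t = ln(K1)/k1 -> half of Rmax
        t_mid = math.log(9.0) / 0.01
        assert root_length(t_mid, toy_params) == pytest.approx(0.5)

    def test_root_length_strictly_increasing(self, toy_params):
        # over the cultivation horizon (strictness saturates in float64
        # far beyond the asymptote)
        t = np.linspace(0, 1296, 400)
        assert np.all(np.diff(root_length(t, toy_params)) > 0)

    def test_root_surface_area(self):
        assert root_surface_area(0.0, 5e-4) == 0.0
        assert root_surface_area(10.0, 5e-4) == pytest.approx(
            2 * math.pi * 5e-4 * 10, rel=1e-12)
        assert root_surface_area(20.0, 5e-4) == pytest.approx(
            2 * root_surface_area(10.0, 5e-4))
        with pytest.raises(ValueError):
            root_surface_area(-1.0, 5e-4)

    def test_lai_midpoint_and_asymptote(self, toy_params):
        assert leaf_area_index(600.0, toy_params) == pytest.approx(1.5)
        assert leaf_area_index(1e7, toy_params) == pytest.approx(3.0)
        # hand value: t = x0 + b_lai -> a/(1+e^-1)
        assert leaf_area_index(720.0, toy_params) == pytest.approx(
            3.0 / (1 + math.exp(-1)), rel=1e-12)

    def test_lai_strictly_increasing_bounded(self, toy_params):
        t = np.linspace(0, 1296, 500)
        lai = leaf_area_index(t, toy_params)
        assert np.all(np.diff(lai) > 0)
        assert np.all((lai > 0) & (lai < 3.0))


class TestUptake:
    def test_zero_substrate(self, toy_params):
        assert np.all(uptake_rate(np.zeros(N_IONS), 0.01, toy_params) == 0)

    def test_half_saturation(self, toy_params):
        j = uptake_rate(toy_params.km, 0.01, toy_params)
        assert j == pytest.approx(0.01 * toy_params.jmax / 2, rel=1e-12)

    def test_hand_value(self, toy_params):
        # P_RSA=0.01, Jmax=2e-5, Km=0.5, C=1.0 -> 1.3333e-7 mol/h
        j = uptake_rate(np.full(N_IONS, 1.0), 0.01, toy_params)
        assert j[0] == pytest.approx(1.3333e-7, rel=1e-4)

    def test_saturation_bound_and_monotonicity(self, toy_params):
        c_grid = np.linspace(0, 50, 200)
        j = np.array([uptake_rate(np.full(N_IONS, c), 0.01, toy_params)[0]
                      for c in c_grid])
        assert np.all(j < 0.01 * toy_params.jmax[0])
        assert np.all(np.diff(j) > 0)
        assert np.all(np.diff(np.diff(j)) < 1e-18)  # concave


class TestTranspiration:
    def test_zero_lai(self, toy_params):
        assert transpiration_rate(500.0, 2.0, 0.0, toy_params) == 0.0

    def test_night_aerodynamic_only(self, toy_params):
        q = transpiration_rate(0.0, 1.0, 2.0, toy_params)
        assert q == pytest.approx(5e-6 * 2.0 * 1.0, rel=1e-12)

    def test_hand_value(self, toy_params):
        q = transpiration_rate(100.0, 1.2, 2.0, toy_params)
        expected = 1e-7 * (1 - math.exp(-1.4)) * 100 + 5e-6 * 2 * 1.2
        assert q == pytest.approx(expected, rel=1e-12)
        assert q == pytest.approx(1.9534e-5, rel=1e-4)


class TestDerivatives:
    def test_closed_system(self, toy_params):
        p = toy_params.with_(jmax=np.full(N_IONS, 1e-300),
                             a_trs=1e-300, b_trs=1e-300)
        state = TankState.from_concentrations(0.0, 0.3, np.ones(N_IONS))
        dv, dm = system_derivatives(state, (0.0, 0.0), None, p)
        assert dv == pytest.approx(0.0, abs=1e-280)
        assert np.allclose(dm, 0.0, atol=1e-280)

    def test_sign_contract(self, toy_params):
        state = TankState.from_concentrations(100.0, 0.3, np.ones(N_IONS))
        dv, dm = system_derivatives(state, (100.0, 1.0), None, toy_params)
        assert dv < 0
        assert np.all(dm < 0)

    def test_empty_tank_rejected(self, toy_params):
        state = TankState(0.0, 0.0, np.zeros(N_IONS))
        with pytest.raises(ValueError):
            system_derivatives(state, (0.0, 0.0), None, toy_params)


class TestIntegrate:
    def test_constant_state_without_fluxes(self, dark_env):
        p = PlantParams(jmax=np.full(N_IONS, 1e-300),
                        km=np.full(N_IONS, 0.5), rmax=1.0, K1=9.0,
                        k1=0.01, r0=5e-4, a_lai=3.0, b_lai=120.0, x0=600.0,
                        a_trs=1e-300, b_trs=1e-300, k_ext=0.7, n_plants=1)
        s0 = TankState.from_concentrations(0.0, 0.3, np.ones(N_IONS))
        res = integrate(s0, p, dark_env, horizon=100.0, dt=0.5)
        assert np.allclose(res.volume, 0.3, rtol=1e-12)
        assert np.allclose(res.mass, 0.3, rtol=1e-12)

    def test_linear_volume_decline_constant_transpiration(self):
        # Q_trs fixed at 1e-5 via a VPD-only term with constant LAI
        # (large b_lai -> LAI ~ a_lai/2 constant); engineered so that
        # n*Q_trs = 8.4e-4 m3/h exactly at LAI=1, VPD=2.
        p = PlantParams(jmax=np.full(N_IONS, 1e-300),
                        km=np.full(N_IONS, 0.5), rmax=1.0, K1=1e-9,
                        k1=1e-9, r0=5e-4, a_lai=2.0, b_lai=1e9, x0=1.0,
                        a_trs=1e-300, b_trs=5e-6, k_ext=0.7, n_plants=84)
        env = ConstantEnvironment(0.0, 2.0)
        s0 = TankState.from_concentrations(0.0, 1.0, np.ones(N_IONS))
        res = integrate(s0, p, env, horizon=100.0, dt=0.5)
        expected = 1.0 - 84 * 1e-5 * res.t
        assert np.allclose(res.volume, expected, rtol=1e-10)

    def test_mass_conservation_stochastic_run(self, pakchoi,
                                              stochastic_schedule):
        from rhizodose.dosing import DosingPolicy
        from rhizodose.environment import stochastic_weather_trajectory
        from rhizodose.synthetic_data import STEINER_MEAN_MOL_M3
        env = stochastic_weather_trajectory(stochastic_schedule, 336.0,
                                            0.5, seed=7)
        policy = DosingPolicy(kind="ec_volume", feed=STEINER_MEAN_MOL_M3,
                              v0=0.3, ec0=26.1)
        s0 = TankState.from_concentrations(0.0, 0.3, STEINER_MEAN_MOL_M3)
        res = integrate(s0, pakchoi, env, policy, horizon=336.0, dt=0.5)
        assert np.max(np.abs(res.mass_balance_residual())) < 1e-6
        # water balance
        v_expect = (res.volume[0] + res.total_dosed_water
                    - pakchoi.n_plants * res.cum_transpiration[-1])
        assert res.volume[-1] == pytest.approx(v_expect, rel=1e-9)

    def test_cumulative_series_monotone(self, pakchoi, room_env,
                                        steiner_state):
        res = integrate(steiner_state, pakchoi, room_env, horizon=168.0,
                        dt=0.5)
        assert np.all(np.diff(res.t) > 0)
        assert np.all(np.diff(res.cum_transpiration) >= 0)
        assert np.all(np.diff(res.cum_uptake, axis=0) >= -1e-15)
        assert np.all(res.volume >= 0)
        assert np.all(res.mass >= 0)

    def test_weekly_sawtooth_volume(self, pakchoi, room_env):
        """Weekly replacement gives declining volume within a week that
        resets at each replacement."""
        from rhizodose.synthetic_data import STEINER_MEAN_MOL_M3
        state = TankState.from_concentrations(0.0, 0.3, STEINER_MEAN_MOL_M3)
        mins = []
        for _ in range(3):
            res = integrate(state, pakchoi, room_env, horizon=168.0, dt=1.0)
            assert res.volume[-1] < res.volume[0]
            mins.append(res.volume[-1])
            end = TankState(res.t[-1], res.volume[-1], res.mass[-1])
            state, _ = weekly_replacement(end, STEINER_MEAN_MOL_M3, 0.3)
            assert state.volume == 0.3
        # drawdown deepens as plants grow
        assert mins[2] < mins[0]

    def test_concentration_literal_form_runs_and_differs(self, pakchoi, room_env,
                                                 steiner_state):
        res_m = integrate(steiner_state, pakchoi, room_env, horizon=168.0,
                          dt=0.5, ode_form="mass")
        res_l = integrate(steiner_state, pakchoi, room_env, horizon=168.0,
                          dt=0.5, ode_form="concentration_literal")
        # the literal form omits the dilution term, so concentrations
        # do not rise with transpiration the way the mass form's do
        assert not np.allclose(res_m.conc[-1], res_l.conc[-1], rtol=1e-3)


class TestWeeklyReplacement:
    def test_idempotent_on_fresh_state(self):
        comp = np.ones(N_IONS)
        s = TankState.from_concentrations(0.0, 0.3, comp)
        fresh, waste = weekly_replacement(s, comp, 0.3)
        assert fresh.volume == s.volume
        assert np.allclose(fresh.mass, s.mass)
        assert waste["water_m3"] == pytest.approx(0.3)

    def test_hand_mass(self):
        s = TankState(0.0, 0.2, np.ones(N_IONS))
        comp = np.zeros(N_IONS)
        comp[0] = 7.5
        fresh, waste = weekly_replacement(s, comp, 0.3)
        assert fresh.mass[0] == pytest.approx(2.25)
        assert np.allclose(waste["nutrients_mol"], 1.0)

    def test_total_equivalents_match_fill(self):
        from rhizodose.dosing import compute_total_equivalents
        s = TankState(0.0, 0.25, np.ones(N_IONS))
        comp = np.array([7.5, 3.0, 2.5, 4.0, 1.9, 1.4])
        fresh, _ = weekly_replacement(s, comp, 0.3)
        assert compute_total_equivalents(fresh.concentrations) == \
            pytest.approx(compute_total_equivalents(comp), rel=1e-12)


def test_params_validation():
    with pytest.raises(ValueError):
        PlantParams(jmax=np.ones(N_IONS), km=np.ones(N_IONS), rmax=-1.0,
                    K1=9.0, k1=0.01, r0=5e-4, a_lai=3.0, b_lai=120.0,
                    x0=600.0, a_trs=1e-7, b_trs=5e-6, k_ext=0.7)
    with pytest.raises(ValueError):
        PlantParams(jmax=np.ones(N_IONS), km=np.ones(N_IONS), rmax=1.0,
                    K1=9.0, k1=0.01, r0=5e-4, a_lai=3.0, b_lai=120.0,
                    x0=600.0, a_trs=1e-7, b_trs=5e-6, k_ext=0.7,
                    n_plants=0)
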