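"""Environment schedules, physical conversions, and random-walk weather."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizodose.environment import (EnvironmentSchedule, WeatherTrajectory,
                                   calibrate_irradiance_scale,
                                   controlled_room_trajectory,
                                   irradiance_under_cloud, ppfd_to_irradiance,
                                   random_walk_cloud, random_walk_vpd,
                                   solar_elevation,
                                   stochastic_weather_trajectory,
                                   vpd_from_temp_rh)


class TestConversions:
    def test_ppfd_to_irradiance(self):
        assert ppfd_to_irradiance(0.0) == 0.0
        assert ppfd_to_irradiance(120.0, 4.6) == pytest.approx(26.087,
                                                               rel=1e-4)
        # round trip
        assert ppfd_to_irradiance(120.0, 4.6) * 4.6 == pytest.approx(120.0)
        with pytest.raises(ValueError):
            ppfd_to_irradiance(120.0, 0.0)

    def test_vpd_saturated_air(self):
        for t in (0.0, 15.0, 30.0):
            assert vpd_from_temp_rh(t, 100.0) == pytest.approx(0.0)

    def test_vpd_hand_values(self):
        # Tetens: es(23) = 2.810 kPa -> x 0.40; es(20) = 2.338 -> x 0.27
        assert vpd_from_temp_rh(23.0, 60.0) == pytest.approx(1.124, abs=2e-3)
        assert vpd_from_temp_rh(20.0, 73.0) == pytest.approx(0.631, abs=2e-3)
        with pytest.raises(ValueError):
            vpd_from_temp_rh(20.0, 101.0)


class TestSolarGeometry:
    def test_equator_equinox_noon(self):
        # day 80 ~ March equinox: sun nearly overhead at the equator
        elev = solar_elevation(12.0, 0.0, 80)
        assert elev > 85.0

    def test_midnight_negative(self):
        assert solar_elevation(0.0, 37.8, 172) < 0

    def test_solstice_noon_hand_value(self):
        # lat 37.8, day 172 (June solstice): 90 - |37.8 - 23.44|
        elev = solar_elevation(12.0, 37.8, 172)
        assert elev == pytest.approx(90 - (37.8 - 23.44), abs=0.5)


class TestCloudIrradiance:
    def test_night_is_dark(self):
        assert irradiance_under_cloud(-5.0, 0.0) == 0.0
        assert irradiance_under_cloud(0.0, 0.0) == 0.0

    def test_clear_sky_zenith(self):
        assert irradiance_under_cloud(90.0, 0.0, 1.0) == pytest.approx(880.0)

    def test_overcast_factor(self):
        clear = irradiance_under_cloud(60.0, 0.0, 1.0)
        overcast = irradiance_under_cloud(60.0, 8.0, 1.0)
        assert overcast == pytest.approx(0.25 * clear, rel=1e-12)

    def test_cloud_range_enforced(self):
        with pytest.raises(ValueError):
            irradiance_under_cloud(45.0, 9.0)


class TestRandomWalks:
    def test_zero_step_constant(self):
        cloud = random_walk_cloud(100.0, 1.0, step=0.0, seed=1, start=4.0)
        assert np.all(cloud == 4.0)
        vpd = random_walk_vpd(100.0, 1.0, step=0.0, seed=1, start=1.0)
        assert np.all(vpd == 1.0)

    def test_determinism(self):
        a = random_walk_vpd(500.0, 0.5, seed=42)
        b = random_walk_vpd(500.0, 0.5, seed=42)
        assert np.array_equal(a, b)
        c = random_walk_vpd(500.0, 0.5, seed=43)
        assert not np.array_equal(a, c)

    def test_reflection_bounds_many_seeds(self):
        """Reflected walks stay in bounds for 1000 seeds (54-day grid)."""
        for seed in range(1000):
            vpd = random_walk_vpd(1296.0, 2.0, seed=seed)
            assert vpd.min() >= 0.5 and vpd.max() <= 2.0
            cloud = random_walk_cloud(1296.0, 2.0, seed=seed)
            assert cloud.min() >= 0.0 and cloud.max() <= 8.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(step=st.floats(0.01, 2.0), seed=st.integers(0, 2**31 - 1))
    def test_reflection_property(self, step, seed):
        vpd = random_walk_vpd(200.0, 0.5, step=step, seed=seed)
        assert np.all((vpd >= 0.5) & (vpd <= 2.0))


class TestControlledRoom:
    def test_square_wave(self, schedule):
        env = controlled_room_trajectory(schedule, 48.0, 0.5)
        t = np.arange(0, 48.0, 0.25)
        k, vpd = env.sample(t)
        lit = k > 0
        # 14 of every 24 hours are lit
        assert lit[: 4 * 14].all() and not lit[4 * 14: 4 * 24].any()
        assert k[0] == pytest.approx(120 / 4.6, rel=1e-9)
        assert vpd[0] == pytest.approx(vpd_from_temp_rh(23, 60))
        assert vpd[4 * 15] == pytest.approx(vpd_from_temp_rh(20, 73))

    def test_photoperiod_must_sum_to_24(self):
        with pytest.raises(ValueError):
            EnvironmentSchedule(hours_light=14, hours_dark=11)


class TestStochasticTrajectory:
    def test_seeded_reproducibility(self, stochastic_schedule):
        a = stochastic_weather_trajectory(stochastic_schedule, 240.0, 0.5,
                                          seed=5)
        b = stochastic_weather_trajectory(stochastic_schedule, 240.0, 0.5,
                                          seed=5)
        assert np.array_equal(a.k_plus, b.k_plus)
        assert np.array_equal(a.vpd, b.vpd)
        assert np.array_equal(a.cloud, b.cloud)

    def test_invariants(self, stochastic_schedule):
        wt = stochastic_weather_trajectory(stochastic_schedule, 240.0, 0.5,
                                           seed=9)
        assert np.all(wt.k_plus >= 0)
        assert np.all((wt.vpd >= 0.5) & (wt.vpd <= 2.0))
        assert np.all((wt.cloud >= 0) & (wt.cloud <= 8))

    def test_csv_round_trip(self, stochastic_schedule, tmp_path):
        wt = stochastic_weather_trajectory(stochastic_schedule, 48.0, 0.5,
                                           seed=3)
        path = tmp_path / "weather.csv"
        wt.to_frame().to_csv(path, index=False)
        import pandas as pd
        back = WeatherTrajectory.from_frame(pd.read_csv(path))
        assert np.allclose(back.k_plus, wt.k_plus)
        assert np.allclose(back.vpd, wt.vpd)

    def test_calibrated_scale_brackets_room_transpiration(
            self, pakchoi, schedule, stochastic_schedule):
        """With the calibrated irradiance scale, the stochastic-weather
        transpiration ensemble overlaps the controlled-room range."""
        from rhizodose.model_core import leaf_area_index, transpiration_rate
        scale = calibrate_irradiance_scale(stochastic_schedule, pakchoi)
        sch = EnvironmentSchedule(mode="stochastic",
                                  irradiance_scale=scale)
        room = controlled_room_trajectory(schedule, 336.0, 0.5)
        t = 0.5 * np.arange(672)  # 14 days at half-hour resolution
        lai = leaf_area_index(t, pakchoi)
        k, v = room.sample(t)
        q_room = transpiration_rate(k, v, lai, pakchoi)
        daily_room = q_room.reshape(14, 48).mean(axis=1)
        medians = []
        for seed in range(5):
            wt = stochastic_weather_trajectory(sch, 336.0, 0.5, seed=seed)
            k2, v2 = wt.sample(t)
            q = transpiration_rate(k2, v2, lai, pakchoi)
            medians.append(np.median(q.reshape(14, 48).mean(axis=1)))
        med = np.median(medians)
        assert daily_room.min() <= med <= daily_room.max()
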