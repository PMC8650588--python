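"""Environment drivers: controlled-room schedules and a stochastic
weather generator.

Two modes supply the (irradiance K+, vapor pressure deficit VPD) forcing
that drives transpiration:

* ``controlled`` — the growth-room regime used for parameter estimation:
  a 14 h / 10 h photoperiod at a PPFD setpoint (converted to W m-2), with
  day/night temperature and relative-humidity setpoints converted to VPD
  through the Tetens saturation-vapor-pressure curve.

* ``stochastic`` — outdoor-like forcing: a Kasten-Czeplak clear-sky
  irradiance model on solar elevation, attenuated by a total cloud cover
  that moves as a reflected random walk on [0, 8] okta, with VPD an
  independent reflected random walk on [0.5, 2.0] kPa.  A global scaling
  factor knocks the irradiance down so simulated transpiration brackets
  the growth-room rates; :func:`calibrate_irradiance_scale` tunes it.

Both produce a :class:`WeatherTrajectory`, which the integrator samples
by linear interpolation, so runs are replayable from the stored CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentSchedule",
    "WeatherTrajectory",
    "ppfd_to_irradiance",
    "vpd_from_temp_rh",
    "solar_elevation",
    "irradiance_under_cloud",
    "random_walk_cloud",
    "random_walk_vpd",
    "controlled_room_trajectory",
    "stochastic_weather_trajectory",
    "calibrate_irradiance_scale",
]

#: PPFD -> shortwave irradiance conversion (umol J-1), warm-white-class source.
DEFAULT_K_CONV = 4.6

#: Kasten-Czeplak clear-sky constants (W m-2): K_clear = A*sin(h) - B.
CLEAR_SKY_A = 910.0
CLEAR_SKY_B = 30.0


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Configuration for either environment mode.

    Controlled-mode setpoints default to the growth-room regime: PPFD
    120 umol m-2 s-1 for 14 h/day, 23 C / 60% RH by day and 20 C / 73%
    RH by night.
    """

    mode: str = "controlled"
    hours_light: float = 14.0
    hours_dark: float = 10.0
    ppfd: float = 120.0
    temp_day: float = 23.0
    temp_night: float = 20.0
    rh_day: float = 60.0
    rh_night: float = 73.0
    k_conv: float = DEFAULT_K_CONV
    latitude: float = 37.8
    day_of_year: int = 172
    irradiance_scale: float = 0.05
    cloud_step: float = 0.5      # okta per sqrt(h)
    vpd_step: float = 0.05       # kPa per sqrt(h)
    vpd_bounds: tuple[float, float] = (0.5, 2.0)
    clear_sky_a: float = CLEAR_SKY_A
    clear_sky_b: float = CLEAR_SKY_B
    seed: int | None = None

    def __post_init__(self):
        if abs(self.hours_light + self.hours_dark - 24.0) > 1e-9:
            raise ValueError("photoperiod must sum to 24 h")
        lo, hi = self.vpd_bounds
        if not (0 < lo < hi):
            raise ValueError("VPD bounds must satisfy 0 < lo < hi")
        if not (0 < self.irradiance_scale <= 1):
            raise ValueError("irradiance scale must be in (0, 1]")
        if self.mode not in ("controlled", "stochastic"):
            raise ValueError(f"unknown mode: {self.mode}")


@dataclass
class WeatherTrajectory:
    """Gridded (K+, VPD) forcing; sampled by linear interpolation."""

    t: np.ndarray
    k_plus: np.ndarray
    vpd: np.ndarray
    cloud: np.ndarray | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if np.any(self.k_plus < 0):
            raise ValueError("irradiance must be >= 0")

    def sample(self, times):
        times = np.asarray(times, dtype=float)
        k = np.interp(times, self.t, self.k_plus)
        v = np.interp(times, self.t, self.vpd)
        return k, v

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.t, "k_plus_w_m2": self.k_plus,
                "vpd_kpa": self.vpd}
        if self.cloud is not None:
            data["cloud_okta"] = self.cloud
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int | None = None
                   ) -> "WeatherTrajectory":
        cloud = df["cloud_okta"].to_numpy() if "cloud_okta" in df else None
        return cls(t=df["time_h"].to_numpy(),
                   k_plus=df["k_plus_w_m2"].to_numpy(),
                   vpd=df["vpd_kpa"].to_numpy(), cloud=cloud, seed=seed)


class SquareWaveEnvironment:
    """Exact day/night square wave (no interpolation smearing at the
    light/dark transitions); used by the controlled mode."""

    def __init__(self, schedule: EnvironmentSchedule):
        self.schedule = schedule
        self.k_day = ppfd_to_irradiance(schedule.ppfd, schedule.k_conv)
        self.vpd_day = vpd_from_temp_rh(schedule.temp_day, schedule.rh_day)
        self.vpd_night = vpd_from_temp_rh(schedule.temp_night, schedule.rh_night)

    def sample(self, times):
        times = np.asarray(times, dtype=float)
        hour = np.mod(times, 24.0)
        is_day = hour < self.schedule.hours_light
        k = np.where(is_day, self.k_day, 0.0)
        v = np.where(is_day, self.vpd_day, self.vpd_night)
        return k, v


# ---------------------------------------------------------------------------
# physical conversions


def ppfd_to_irradiance(ppfd: float, k_conv: float = DEFAULT_K_CONV):
    """PPFD (umol m-2 s-1) -> shortwave irradiance (W m-2) via the
    source-specific quantum yield k_conv (umol J-1)."""
    if k_conv <= 0:
        raise ValueError("k_conv must be positive")
    ppfd = np.asarray(ppfd, dtype=float)
    if np.any(ppfd < 0):
        raise ValueError("PPFD must be >= 0")
    return ppfd / k_conv


def saturation_vapor_pressure(temp_c):
    """Tetens curve es(T) = 0.6108 * exp(17.27 T / (T + 237.3)) kPa."""
    temp_c = np.asarray(temp_c, dtype=float)
    return 0.6108 * np.exp(17.27 * temp_c / (temp_c + 237.3))


def vpd_from_temp_rh(temp_c, rh_percent):
    """Vapor pressure deficit (kPa) from air temperature and RH."""
    rh = np.asarray(rh_percent, dtype=float)
    if np.any((rh < 0) | (rh > 100)):
        raise ValueError("relative humidity must be within [0, 100]%")
    return saturation_vapor_pressure(temp_c) * (1.0 - rh / 100.0)


def solar_elevation(t, latitude: float, day_of_year: int):
    """Solar elevation angle (deg) at elapsed hour ``t`` (t=0 is local
    midnight of ``day_of_year``; the date advances with t).

    Uses the standard declination approximation
    delta = 23.44 * sin(2*pi*(284 + doy)/365) and the hour angle from
    local solar time.
    """
    t = np.asarray(t, dtype=float)
    doy = day_of_year + np.floor(t / 24.0)
    decl = np.radians(23.44) * np.sin(2 * np.pi * (284 + doy) / 365.0)
    hour_angle = np.radians(15.0 * (np.mod(t, 24.0) - 12.0))
    lat = math.radians(latitude)
    sin_h = (np.sin(lat) * np.sin(decl)
             + np.cos(lat) * np.cos(decl) * np.cos(hour_angle))
    return np.degrees(np.arcsin(np.clip(sin_h, -1.0, 1.0)))


def irradiance_under_cloud(elevation, cloud_okta, scale: float = 1.0, *,
                           a: float = CLEAR_SKY_A, b: float = CLEAR_SKY_B):
    """Global irradiance (W m-2) under total cloud cover N (okta).

    Kasten-Czeplak: K = scale * max(0, A*sin(h) - B) * (1 - 0.75*(N/8)^3.4).
    """
    cloud = np.asarray(cloud_okta, dtype=float)
    if np.any((cloud < 0) | (cloud > 8)):
        raise ValueError("cloud cover must be within [0, 8] okta")
    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    elev = np.radians(np.asarray(elevation, dtype=float))
    clear = np.maximum(0.0, a * np.sin(elev) - b)
    clear = np.where(np.asarray(elevation) <= 0, 0.0, clear)
    return scale * clear * (1.0 - 0.75 * (cloud / 8.0) ** 3.4)


# ---------------------------------------------------------------------------
# random walks


def _reflected_walk(n: int, dt: float, step: float, lo: float, hi: float,
                    start: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian random walk with reflecting barriers at [lo, hi].

    Increments are N(0, step^2 * dt) so the step parameter is a rate per
    sqrt(hour) and trajectories are grid-refinement consistent.
    """
    if not lo <= start <= hi:
        raise ValueError("walk start must lie within bounds")
    increments = rng.normal(0.0, step * math.sqrt(dt), size=n)
    x = start + np.cumsum(increments)
    out = np.empty(n + 1)
    out[0] = start
    out[1:] = x
    # reflect into [lo, hi]: fold the unbounded walk
    span = hi - lo
    y = np.mod(out - lo, 2 * span)
    out = lo + np.where(y > span, 2 * span - y, y)
    return out


def random_walk_cloud(horizon: float, dt: float, step: float = 0.5,
                      seed: int | None = None, start: float = 4.0
                      ) -> np.ndarray:
    """Reflected random-walk total cloud cover series on [0, 8] okta."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(horizon / dt))
    return _reflected_walk(n, dt, step, 0.0, 8.0, start, rng)


def random_walk_vpd(horizon: float, dt: float, step: float = 0.05,
                    bounds: tuple[float, float] = (0.5, 2.0),
                    seed: int | None = None, start: float | None = None
                    ) -> np.ndarray:
    """Reflected random-walk VPD series within ``bounds`` (kPa)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    lo, hi = bounds
    if not lo < hi:
        raise ValueError("VPD bounds must be ordered")
    rng = np.random.default_rng(seed)
    n = int(round(horizon / dt))
    if start is None:
        start = 0.5 * (lo + hi)
    return _reflected_walk(n, dt, step, lo, hi, start, rng)


# ---------------------------------------------------------------------------
# trajectory assembly


def controlled_room_trajectory(schedule: EnvironmentSchedule,
                               horizon: float, dt: float
                               ) -> SquareWaveEnvironment:
    """Day/night square-wave forcing for the growth-room regime.

    Returns a sampler (exact square wave); use ``gridded=True`` output of
    :meth:`to_weather` if a CSV-serialisable grid is needed.
    """
    del horizon, dt  # the square wave is analytic; kept for API symmetry
    return SquareWaveEnvironment(schedule)


def stochastic_weather_trajectory(schedule: EnvironmentSchedule,
                                  horizon: float, dt: float,
                                  seed: int | None = None
                                  ) -> WeatherTrajectory:
    """Random-walk cloud cover over clear-sky irradiance + random-walk VPD."""
    if seed is None:
        seed = schedule.seed
    rng = np.random.default_rng(seed)
    n = int(round(horizon / dt))
    t = dt * np.arange(n + 1)
    cloud = _reflected_walk(n, dt, schedule.cloud_step, 0.0, 8.0, 4.0, rng)
    lo, hi = schedule.vpd_bounds
    vpd = _reflected_walk(n, dt, schedule.vpd_step, lo, hi,
                          0.5 * (lo + hi), rng)
    elev = solar_elevation(t, schedule.latitude, schedule.day_of_year)
    k_plus = irradiance_under_cloud(elev, cloud, schedule.irradiance_scale,
                                    a=schedule.clear_sky_a,
                                    b=schedule.clear_sky_b)
    return WeatherTrajectory(t=t, k_plus=k_plus, vpd=vpd, cloud=cloud,
                             seed=seed,
                             meta={"mode": "stochastic",
                                   "scale": schedule.irradiance_scale})


def calibrate_irradiance_scale(schedule: EnvironmentSchedule, params,
                               horizon: float = 336.0, dt: float = 0.5,
                               n_seeds: int = 5, seed: int = 0) -> float:
    """Choose the irradiance scaling factor so the stochastic-weather mean
    transpiration matches the controlled-room mean for the same plants.

    The transpiration model is linear in K+, so the matching scale solves
    a single linear equation per seed; the seed-mean is returned.
    """
    from .model_core import leaf_area_index, transpiration_rate

    room = SquareWaveEnvironment(schedule)
    t = dt * np.arange(int(round(horizon / dt)) + 1)
    lai = leaf_area_index(t, params)
    k_room, vpd_room = room.sample(t)
    target = transpiration_rate(k_room, vpd_room, lai, params).mean()

    scales = []
    for i in range(n_seeds):
        probe = stochastic_weather_trajectory(
            schedule, horizon, dt, seed=seed + i)
        k_unit = probe.k_plus / schedule.irradiance_scale  # unscaled clear-sky*cloud
        base = transpiration_rate(np.zeros_like(k_unit), probe.vpd, lai,
                                  params).mean()
        radiative_unit = transpiration_rate(k_unit, probe.vpd, lai, params
                                            ).mean() - base
        if radiative_unit <= 0:
            continue
        scales.append(min(1.0, max(1e-4, (target - base) / radiative_unit)))
    if not scales:
        raise RuntimeError("cannot calibrate: radiative term is degenerate")
    return float(np.mean(scales))
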