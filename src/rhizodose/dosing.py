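"""Nutrient dosing controllers and total-ionic-equivalent (EC) arithmetic.

Three fertigation controllers are compared throughout the package; none
ever removes solution from the tank (the emission-free contract):

* ``volume``   — top the tank back up to its initial volume V0 with the
  standard feed solution; nutrient input therefore tracks whatever water
  transpiration removed since the last dosing time.
* ``time``     — add a fixed amount of nutrients at every dosing time,
  regardless of tank state (water is still topped up to V0 — the
  controllers differ in their *nutrient* logic, water level control
  being common practice; set ``top_up_water=False`` for a literal
  fixed-water dose).
* ``ec_volume``— restore the tank's *total ionic equivalents* to the
  setpoint V0*EC0 (the feed composition sets only the ratio among ions)
  and top water up to V0.  EC is carried as equivalent concentration
  (eq m-3, numerically meq L-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .ions import N_IONS, VALENCES, nutrient_vector
from .model_core import TankState

__all__ = [
    "DosingPolicy",
    "DoseEvent",
    "compute_total_equivalents",
    "volume_based_dose",
    "time_based_dose",
    "ec_volume_based_dose",
    "apply_dose",
    "compute_dose_arrays",
    "calibrate_time_dose",
]

#: display-only conversion between equivalent concentration and conductivity
DS_PER_MEQ = 0.1  # dS m-1 per meq L-1


def compute_total_equivalents(conc) -> float:
    """Total ionic equivalent concentration sum(|z_I| * C_I) in eq m-3
    (numerically equal to meq L-1).  Broadcasts over leading axes."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    out = conc @ VALENCES
    return float(out) if out.ndim == 0 else out


def equivalents_to_ds_m(ec_eq_m3: float) -> float:
    """Reporting helper: equivalent concentration -> approximate dS m-1."""
    return ec_eq_m3 * DS_PER_MEQ


@dataclass(frozen=True)
class DosingPolicy:
    """Controller configuration shared by the three dosing methods.

    ``feed`` (mol m-3) is the standard feed solution for the volume
    controller; for ``ec_volume`` only its ratio matters (additions are
    scaled on the equivalent scale to hit the EC setpoint exactly).
    ``fixed_dose_*`` apply to the time controller only.
    """

    kind: str
    interval: float = 24.0
    feed: np.ndarray = field(default_factory=lambda: np.zeros(N_IONS))
    v0: float = 0.3
    ec0: float = 26.1
    fixed_dose_water: float = 0.0
    fixed_dose_nutrients: np.ndarray = field(
        default_factory=lambda: np.zeros(N_IONS))
    top_up_water: bool = True

    def __post_init__(self):
        if self.kind not in ("volume", "time", "ec_volume"):
            raise ValueError(f"unknown dosing kind: {self.kind}")
        if self.interval <= 0:
            raise ValueError("dosing interval must be positive")
        if self.v0 <= 0:
            raise ValueError("V0 must be positive")
        feed = nutrient_vector(self.feed)
        object.__setattr__(self, "feed", feed)
        object.__setattr__(self, "fixed_dose_nutrients",
                           nutrient_vector(self.fixed_dose_nutrients))
        if self.fixed_dose_water < 0:
            raise ValueError("fixed dose water must be >= 0")
        if self.kind in ("volume", "ec_volume") and not np.any(feed > 0):
            raise ValueError("feed composition must not be all-zero")

    def with_(self, **kw) -> "DosingPolicy":
        return replace(self, **kw)

    def describe(self) -> dict:
        return {"kind": self.kind, "interval_h": self.interval,
                "v0_m3": self.v0, "ec0_eq_m3": self.ec0}


@dataclass(frozen=True)
class DoseEvent:
    """One instantaneous addition of water (m3) and nutrients (mol)."""

    time: float
    water: float
    nutrients: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "nutrients",
                           nutrient_vector(self.nutrients))
        if self.water < 0:
            raise ValueError("dose water must be >= 0")


# ---------------------------------------------------------------------------
# controllers (vectorised core + TankState wrappers)


def _volume_dose_arrays(v, m, policy):
    del m
    deficit = policy.v0 - v
    if np.any(deficit < -1e-12):
        warnings.warn("tank volume above V0; volume-based dose is zero",
                      stacklevel=3)
    water = np.maximum(deficit, 0.0)
    return water, water[:, None] * policy.feed


def _time_dose_arrays(v, m, policy):
    del m
    batch = v.shape[0]
    if policy.top_up_water:
        water = np.maximum(policy.v0 - v, 0.0)
    else:
        water = np.full(batch, policy.fixed_dose_water)
    nutr = np.broadcast_to(policy.fixed_dose_nutrients,
                           (batch, N_IONS)).copy()
    return water, nutr


def _ec_volume_dose_arrays(v, m, policy):
    water = np.maximum(policy.v0 - v, 0.0)
    eq_feed = float(policy.feed @ VALENCES)
    if eq_feed <= 0:
        raise ValueError("ec_volume feed must carry positive equivalents")
    unit_ratio = policy.feed / eq_feed          # mol per eq added
    current_eq = m @ VALENCES                   # eq currently in the tank
    deficit = np.maximum(policy.v0 * policy.ec0 - current_eq, 0.0)
    return water, deficit[:, None] * unit_ratio


_CONTROLLERS = {
    "volume": _volume_dose_arrays,
    "time": _time_dose_arrays,
    "ec_volume": _ec_volume_dose_arrays,
}


def compute_dose_arrays(v: np.ndarray, m: np.ndarray,
                        policy: DosingPolicy
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised controller dispatch over a batch of tank states.

    ``v`` (B,) and ``m`` (B, 6) are volumes and nutrient masses; returns
    (water (B,), nutrients (B, 6)), all additions >= 0.
    """
    return _CONTROLLERS[policy.kind](np.atleast_1d(v), np.atleast_2d(m),
                                     policy)


def _single(state: TankState, policy: DosingPolicy) -> DoseEvent:
    w, n = compute_dose_arrays(np.array([state.volume]),
                               state.mass[None, :], policy)
    return DoseEvent(time=state.t, water=float(w[0]), nutrients=n[0])


def volume_based_dose(state: TankState, policy: DosingPolicy) -> DoseEvent:
    """Top up to V0 with the standard feed solution."""
    return _single(state, policy.with_(kind="volume"))


def time_based_dose(policy: DosingPolicy, time: float = 0.0,
                    state: TankState | None = None) -> DoseEvent:
    """The configured fixed nutrient dose, identical at every dosing time.

    The water term is the V0 top-up when ``policy.top_up_water`` and a
    ``state`` is given, else the configured fixed water amount.
    """
    if policy.top_up_water and state is not None:
        water = max(policy.v0 - state.volume, 0.0)
    else:
        water = policy.fixed_dose_water
    return DoseEvent(time=time, water=water,
                     nutrients=policy.fixed_dose_nutrients.copy())


def ec_volume_based_dose(state: TankState, policy: DosingPolicy) -> DoseEvent:
    """Restore total equivalents to V0*EC0 and water volume to V0."""
    return _single(state, policy.with_(kind="ec_volume"))


def apply_dose(state: TankState, dose: DoseEvent) -> TankState:
    """Instantaneous, mass-additive application of a dose."""
    if dose.water < 0 or np.any(dose.nutrients < 0):
        raise ValueError("doses must be non-negative")
    return TankState(t=state.t, volume=state.volume + dose.water,
                     mass=state.mass + dose.nutrients)


# ---------------------------------------------------------------------------
# calibration helper


def calibrate_time_dose(params, env, policy: DosingPolicy, *,
                        state0: Optional[TankState] = None,
                        horizon: float = 1296.0, dt: float = 0.5
                        ) -> DosingPolicy:
    """Set the time controller's fixed dose from an EC+volume reference run.

    Runs the same scenario under ``ec_volume`` dosing and divides the
    cumulative dosed water and nutrients evenly over the dosing events,
    which makes cross-controller comparisons input-matched.
    """
    from .model_core import integrate

    if state0 is None:
        state0 = TankState.from_concentrations(0.0, policy.v0, policy.feed)
    ref = integrate(state0, params, env,
                    policy.with_(kind="ec_volume"),
                    horizon=horizon, dt=dt)
    n_events = max(len(ref.dose_times), 1)
    return policy.with_(
        kind="time",
        fixed_dose_water=ref.total_dosed_water / n_events,
        fixed_dose_nutrients=ref.total_dosed_nutrients / n_events,
    )
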