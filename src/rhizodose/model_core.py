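"""Deterministic hydroponic tank model.

A single well-mixed nutrient tank feeds ``n_plants`` plants.  Plant state
is parametric in elapsed time ``t`` (hours since transplanting): root
length follows a logistic curve, leaf area index (LAI) a Boltzmann
sigmoid.  Per-plant nutrient uptake is Michaelis-Menten in the tank
concentration, scaled by root surface area; per-plant transpiration is a
reduced Penman-Monteith (Baille-type) response to irradiance and vapor
pressure deficit (VPD).  The tank obeys

    dV/dt = Q_in - n * Q_trs
    dM/dt = Q_in * C_in - n * J(C),   C = M / V

i.e. nutrient *mass* M (mol) is the integrated state, so mass is
conserved exactly up to integration error: transpired water carries no
nutrients, and concentration rises whenever transpiration outpaces
uptake.  (A literal form integrating V*dC/dt = Q_in*C_in - n*J, which
omits the dilution term, is kept behind ``ode_form="concentration_literal"`` for
comparison.)

Integration is explicit RK4 on a fixed grid with dosing and replacement
applied as instantaneous events at grid times.  Cumulative per-plant
uptake and transpiration are integrated alongside the state with the
same RK4 stage weights, so the mass- and water-balance residuals of a
run are at machine precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional

import numpy as np

from .ions import N_IONS, nutrient_vector

if TYPE_CHECKING:  # pragma: no cover
    from .dosing import DosingPolicy

__all__ = [
    "PlantParams",
    "TankState",
    "SimulationResult",
    "root_length",
    "root_surface_area",
    "leaf_area_index",
    "uptake_rate",
    "transpiration_rate",
    "system_derivatives",
    "integrate",
    "weekly_replacement",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PlantParams:
    """All per-species plant parameters.

    Units: jmax mol m-2 h-1 (per ion), km mol m-3 (per ion), rmax m,
    K1 dimensionless, k1 h-1, r0 m, a_lai dimensionless, b_lai h, x0 h,
    a_trs m3 h-1 per (W m-2), b_trs m3 h-1 per kPa, k_ext dimensionless.
    """

    jmax: np.ndarray
    km: np.ndarray
    rmax: float
    K1: float
    k1: float
    r0: float
    a_lai: float
    b_lai: float
    x0: float
    a_trs: float
    b_trs: float
    k_ext: float
    n_plants: int = 84
    vpd_in_exponent: bool = False

    def __post_init__(self):
        object.__setattr__(self, "jmax", nutrient_vector(self.jmax))
        object.__setattr__(self, "km", nutrient_vector(self.km))
        for name in ("rmax", "K1", "k1", "r0", "a_lai", "b_lai", "x0",
                     "a_trs", "b_trs", "k_ext"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PlantParams.{name} must be positive")
        if np.any(self.km <= 0):
            raise ValueError("PlantParams.km must be positive")
        if self.n_plants < 1:
            raise ValueError("PlantParams.n_plants must be >= 1")

    def with_(self, **kw) -> "PlantParams":
        return replace(self, **kw)


@dataclass
class TankState:
    """Tank ODE state: elapsed time t (h), water volume (m3), ion masses (mol)."""

    t: float
    volume: float
    mass: np.ndarray

    def __post_init__(self):
        self.mass = nutrient_vector(self.mass)
        if self.volume < 0:
            raise ValueError("tank volume must be >= 0")

    @property
    def concentrations(self) -> np.ndarray:
        """Concentration view C = M / V (mol m-3); requires V > 0."""
        if self.volume <= 0:
            raise ValueError("concentration undefined for empty tank")
        return self.mass / self.volume

    @classmethod
    def from_concentrations(cls, t: float, volume: float, conc) -> "TankState":
        conc = nutrient_vector(conc)
        return cls(t=t, volume=volume, mass=volume * conc)


@dataclass
class SimulationResult:
    """Trajectory of one tank run plus the dosing log and config snapshot."""

    t: np.ndarray                      # (n+1,) hours
    volume: np.ndarray                 # (n+1,) m3
    conc: np.ndarray                   # (n+1, 6) mol m-3
    mass: np.ndarray                   # (n+1, 6) mol
    q_trs: np.ndarray                  # (n+1,) m3 h-1 per plant
    cum_transpiration: np.ndarray      # (n+1,) m3 per plant
    cum_uptake: np.ndarray             # (n+1, 6) mol per plant
    dose_times: np.ndarray             # (k,) h
    dose_water: np.ndarray             # (k,) m3
    dose_nutrients: np.ndarray         # (k, 6) mol
    clipped_mass: float = 0.0
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)

    @property
    def total_dosed_water(self) -> float:
        return float(self.dose_water.sum())

    @property
    def total_dosed_nutrients(self) -> np.ndarray:
        if len(self.dose_times) == 0:
            return np.zeros(N_IONS)
        return self.dose_nutrients.sum(axis=0)

    def mass_balance_residual(self) -> np.ndarray:
        """Per-ion relative residual of M_final - M_0 - dosed + absorbed."""
        n = self.config.get("n_plants", 1)
        absorbed = n * self.cum_uptake[-1]
        dosed = self.total_dosed_nutrients.copy()
        influx = self.config.get("inflow_nutrients_mol")
        if influx is not None:
            dosed = dosed + np.asarray(influx)
        resid = self.mass[-1] - self.mass[0] - dosed + absorbed
        scale = np.maximum(self.mass[0], dosed)
        scale = np.where(scale > 0, scale, 1.0)
        return resid / scale


# ---------------------------------------------------------------------------
# plant submodels


def root_length(t, params: PlantParams):
    """Logistic root length (m): Rmax / (1 + K1 * exp(-k1 * t))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return params.rmax / (1.0 + params.K1 * np.exp(-params.k1 * t))


def root_surface_area(length, r0: float):
    """Root surface area (m2) of a smooth cylinder: 2*pi*r0*length."""
    length = np.asarray(length, dtype=float)
    if np.any(length < 0) or r0 < 0:
        raise ValueError("root length and radius must be >= 0")
    return 2.0 * math.pi * r0 * length


def leaf_area_index(t, params: PlantParams):
    """Boltzmann-sigmoid LAI: a_lai / (1 + exp((x0 - t) / b_lai))."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if params.b_lai == 0:
        raise ValueError("b_lai must be nonzero")
    return params.a_lai / (1.0 + np.exp((params.x0 - t) / params.b_lai))


def uptake_rate(conc, p_rsa, params: PlantParams):
    """Per-plant Michaelis-Menten uptake J = P_RSA * Jmax * C / (Km + C).

    ``conc`` broadcasts against the trailing ion axis; returns mol h-1
    per plant, bounded by P_RSA * Jmax.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    p_rsa = np.asarray(p_rsa, dtype=float)
    if np.any(p_rsa < 0):
        raise ValueError("root surface area must be >= 0")
    return p_rsa * params.jmax * conc / (params.km + conc)


def transpiration_rate(k_plus, vpd, lai, params: PlantParams):
    """Per-plant transpiration (m3 h-1): radiative + aerodynamic terms.

    Default (Baille-type) form a_trs*(1-exp(-k_ext*LAI))*K+ + b_trs*LAI*VPD.
    With ``params.vpd_in_exponent`` the VPD multiplies LAI inside the
    canopy-extinction exponent instead.
    """
    k_plus = np.asarray(k_plus, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(k_plus < 0) or np.any(vpd < 0) or np.any(lai < 0):
        raise ValueError("irradiance, VPD, and LAI must be >= 0")
    if params.vpd_in_exponent:
        intercept = 1.0 - np.exp(-params.k_ext * lai * vpd)
    else:
        intercept = 1.0 - np.exp(-params.k_ext * lai)
    return params.a_trs * intercept * k_plus + params.b_trs * lai * vpd


def system_derivatives(state: TankState, env: tuple[float, float],
                       inflow: tuple[float, np.ndarray] | None,
                       params: PlantParams) -> tuple[float, np.ndarray]:
    """(dV/dt, dM/dt) at ``state`` under environment (K+, VPD) and
    continuous inflow (Q_in, C_in).  Transpired water carries no nutrients."""
    if state.volume <= 0:
        raise ValueError("tank volume must be positive")
    k_plus, vpd = env
    q_in, c_in = (0.0, np.zeros(N_IONS)) if inflow is None else inflow
    c_in = nutrient_vector(c_in)
    prsa = root_surface_area(root_length(state.t, params), params.r0)
    lai = leaf_area_index(state.t, params)
    j = uptake_rate(state.concentrations, prsa, params)
    q_trs = transpiration_rate(k_plus, vpd, lai, params)
    dv = q_in - params.n_plants * float(q_trs)
    dm = q_in * c_in - params.n_plants * j
    return dv, dm


# ---------------------------------------------------------------------------
# integrator


def _plant_rates(t, params: PlantParams):
    """(P_RSA, LAI) at time(s) t."""
    prsa = root_surface_area(root_length(t, params), params.r0)
    lai = leaf_area_index(t, params)
    return prsa, lai


def integrate_batch(v0, m0, params: PlantParams, env, horizon: float,
                    dt: float, policy: "DosingPolicy | None" = None,
                    t0: float = 0.0, ode_form: str = "mass",
                    inflow: tuple[float, np.ndarray] | None = None):
    """Vectorised fixed-step RK4 over a batch of tanks sharing params/policy.

    ``v0`` has shape (B,), ``m0`` shape (B, 6); ``env.sample(times)``
    returns (K+, VPD) arrays broadcastable to (B, len(times)).  Returns a
    dict of raw trajectory arrays (leading batch axis).  ``integrate``
    wraps the B=1 case in a :class:`SimulationResult`.

    ``inflow`` is an optional *continuous* source (q_in m3 h-1,
    f_nutrients mol h-1), constant over the run — dosing events remain
    instantaneous and come from ``policy``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if ode_form not in ("mass", "concentration_literal"):
        raise ValueError(f"unknown ode_form: {ode_form}")
    n_steps = int(round(horizon / dt))
    if abs(n_steps * dt - horizon) > 1e-9 * max(1.0, horizon):
        warnings.warn("horizon is not a multiple of dt; truncating", stacklevel=2)

    v = np.atleast_1d(np.asarray(v0, dtype=float)).copy()
    batch = v.shape[0]
    m = np.asarray(m0, dtype=float).reshape(batch, N_IONS).copy()

    # env sampled once on the half-step grid required by RK4
    t_half = t0 + dt * 0.5 * np.arange(2 * n_steps + 1)
    k_half, vpd_half = env.sample(t_half)
    k_half = np.broadcast_to(np.asarray(k_half, dtype=float), (batch, t_half.size))
    vpd_half = np.broadcast_to(np.asarray(vpd_half, dtype=float), (batch, t_half.size))
    prsa_half, lai_half = _plant_rates(t_half, params)

    n_pl = params.n_plants
    jmax, km = params.jmax, params.km
    if inflow is None:
        q_in, f_in = 0.0, np.zeros(N_IONS)
    else:
        q_in = float(inflow[0])
        f_in = nutrient_vector(inflow[1])
        if q_in < 0:
            raise ValueError("inflow rate must be >= 0")

    dose_times = []
    if policy is not None:
        if policy.interval <= 0:
            raise ValueError("dosing interval must be positive")
        steps_per_dose = policy.interval / dt
        if abs(steps_per_dose - round(steps_per_dose)) > 1e-9:
            raise ValueError("dosing interval must be a multiple of dt")
        steps_per_dose = int(round(steps_per_dose))
    else:
        steps_per_dose = 0

    vol = np.empty((batch, n_steps + 1))
    mass = np.empty((batch, n_steps + 1, N_IONS))
    q_trs_out = np.empty((batch, n_steps + 1))
    cum_trs = np.zeros((batch, n_steps + 1))
    cum_upt = np.zeros((batch, n_steps + 1, N_IONS))
    dose_water_log, dose_nutr_log = [], []
    clipped = np.zeros(batch)

    literal = ode_form == "concentration_literal"
    if literal:
        c_state = m / v[:, None]

    def q_trs_at(idx):
        return transpiration_rate(k_half[:, idx], vpd_half[:, idx],
                                  lai_half[idx], params)

    def uptake_at(idx, conc):
        conc = np.maximum(conc, 0.0)
        return prsa_half[idx] * jmax * conc / (km + conc)

    vol[:, 0] = v
    mass[:, 0] = m
    q_trs_out[:, 0] = q_trs_at(0)

    for step in range(n_steps):
        i0, i1, i2 = 2 * step, 2 * step + 1, 2 * step + 2
        qa, qb, qc = q_trs_at(i0), q_trs_at(i1), q_trs_at(i2)

        if np.any(v <= 0):
            raise RuntimeError(
                f"tank ran dry at t={t0 + step * dt:.2f} h; "
                "reduce horizon or add dosing")

        if literal:
            # V * dC/dt = q_in*C_in - n*J (no dilution term), V separate
            def dc(idx, c, vv):
                return (f_in - n_pl * uptake_at(idx, c)) / vv[:, None]
            v1 = v + dt * 0.5 * (q_in - n_pl * qa)
            v2 = v + dt * 0.5 * (q_in - n_pl * qb)
            v3 = v + dt * (q_in - n_pl * qc)
            k1c = dc(i0, c_state, v)
            k2c = dc(i1, c_state + dt / 2 * k1c, v1)
            k3c = dc(i1, c_state + dt / 2 * k2c, v2)
            k4c = dc(i2, c_state + dt * k3c, v3)
            c_state = c_state + dt / 6 * (k1c + 2 * k2c + 2 * k3c + k4c)
            v = v + dt * q_in - dt / 6 * n_pl * (qa + 4 * qb + qc)
            np.clip(c_state, 0.0, None, out=c_state)
            np.clip(v, 0.0, None, out=v)
            m = c_state * v[:, None]
            u_inc = np.zeros((batch, N_IONS))  # uptake ledger n/a in literal form
        else:
            # mass form; volume decouples from M so its RK4 is exact Simpson
            def dm(idx, mm, vv):
                return f_in - n_pl * uptake_at(idx, mm / vv[:, None])
            v1 = v + dt * 0.5 * (q_in - n_pl * qa)
            v2 = v + dt * 0.5 * (q_in - n_pl * qb)
            v3 = v + dt * (q_in - n_pl * qc)
            k1m = dm(i0, m, v)
            k2m = dm(i1, m + dt / 2 * k1m, np.maximum(v1, 1e-12))
            k3m = dm(i1, m + dt / 2 * k2m, np.maximum(v2, 1e-12))
            k4m = dm(i2, m + dt * k3m, np.maximum(v3, 1e-12))
            dm_step = dt / 6 * (k1m + 2 * k2m + 2 * k3m + k4m)
            m = m + dm_step
            v = v + dt * q_in - dt / 6 * n_pl * (qa + 4 * qb + qc)
            # per-plant uptake increment with identical quadrature weights
            u_inc = (dt * f_in - dm_step) / n_pl
            neg = m < 0
            if np.any(neg):
                clipped += np.where(neg, -m, 0.0).sum(axis=1)
                u_inc = u_inc + np.where(neg, m, 0.0) / n_pl
                m = np.where(neg, 0.0, m)
            np.clip(v, 0.0, None, out=v)

        cum_trs[:, step + 1] = cum_trs[:, step] + dt / 6 * (qa + 4 * qb + qc)
        cum_upt[:, step + 1] = cum_upt[:, step] + u_inc

        # dosing event at the grid time just reached
        if steps_per_dose and (step + 1) % steps_per_dose == 0 and (
                policy is not None):
            from .dosing import compute_dose_arrays
            w, nutr = compute_dose_arrays(v, m, policy)
            v = v + w
            m = m + nutr
            if literal:
                c_state = m / np.maximum(v[:, None], 1e-12)
            dose_times.append(t0 + (step + 1) * dt)
            dose_water_log.append(w.copy())
            dose_nutr_log.append(nutr.copy())

        vol[:, step + 1] = v
        mass[:, step + 1] = m
        q_trs_out[:, step + 1] = qc

    m0_arr = mass[:, 0]
    tot = m0_arr.sum(axis=1)
    bad = clipped > 0.01 * np.where(tot > 0, tot, 1.0)
    if np.any(bad):
        raise RuntimeError(
            "negative-mass clipping exceeded 1% of initial nutrient mass; "
            "decrease dt")
    if np.any(clipped > 0):
        warnings.warn(
            f"clipped {clipped.max():.3g} mol of negative nutrient mass",
            stacklevel=2)

    return {
        "t": t0 + dt * np.arange(n_steps + 1),
        "volume": vol,
        "mass": mass,
        "q_trs": q_trs_out,
        "cum_transpiration": cum_trs,
        "cum_uptake": cum_upt,
        "dose_times": np.array(dose_times),
        "dose_water": (np.stack(dose_water_log, axis=1)
                       if dose_water_log else np.zeros((batch, 0))),
        "dose_nutrients": (np.stack(dose_nutr_log, axis=1)
                           if dose_nutr_log else np.zeros((batch, 0, N_IONS))),
        "clipped_mass": clipped,
    }


def integrate(state0: TankState, params: PlantParams, env,
              policy: "DosingPolicy | None" = None, *,
              horizon: float = 1296.0, dt: float = 0.1,
              ode_form: str = "mass", seed: int | None = None,
              inflow: tuple[float, np.ndarray] | None = None
              ) -> SimulationResult:
    """Integrate one tank from ``state0`` for ``horizon`` hours.

    ``env`` is any object with ``sample(times) -> (K+, VPD)`` (see
    :mod:`rhizodose.environment`).  Dosing events fire every
    ``policy.interval`` hours (never at t0).  Default horizon is the
    54-day cultivation period (1296 h).
    """
    raw = integrate_batch(np.array([state0.volume]),
                          state0.mass[None, :], params, env,
                          horizon, dt, policy=policy, t0=state0.t,
                          ode_form=ode_form, inflow=inflow)
    vol = raw["volume"][0]
    mass = raw["mass"][0]
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = np.where(vol[:, None] > 0, mass / np.where(
            vol[:, None] > 0, vol[:, None], 1.0), np.nan)
    return SimulationResult(
        t=raw["t"],
        volume=vol,
        conc=conc,
        mass=mass,
        q_trs=raw["q_trs"][0],
        cum_transpiration=raw["cum_transpiration"][0],
        cum_uptake=raw["cum_uptake"][0],
        dose_times=raw["dose_times"],
        dose_water=raw["dose_water"][0],
        dose_nutrients=raw["dose_nutrients"][0],
        clipped_mass=float(raw["clipped_mass"][0]),
        seed=seed,
        config={
            "horizon_h": horizon, "dt_h": dt, "ode_form": ode_form,
            "n_plants": params.n_plants,
            "policy": None if policy is None else policy.describe(),
            "inflow_nutrients_mol": (None if inflow is None
                                     else (horizon * nutrient_vector(
                                         inflow[1])).tolist()),
        },
    )


def weekly_replacement(state: TankState, new_composition,
                       v0: float) -> tuple[TankState, dict]:
    """Discard the tank contents and refill to ``v0`` at ``new_composition``.

    Returns the fresh state and a waste record (discarded water and
    moles) for the emission ledger.
    """
    if v0 <= 0:
        raise ValueError("replacement volume must be positive")
    comp = nutrient_vector(new_composition)
    waste = {"water_m3": state.volume, "nutrients_mol": state.mass.copy()}
    fresh = TankState(t=state.t, volume=v0, mass=v0 * comp)
    return fresh, waste
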