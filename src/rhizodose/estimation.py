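"""Depletion-method uptake accounting and progress-curve parameter fitting.

A measurement campaign is a sequence of weekly closed-tank depletion
records: the tank is filled, left untouched for a week while the plants
transpire and absorb, and the initial/final concentrations and volumes
are recorded (the classical N/W bookkeeping: absorption per plant is
``(C_i*V_i - C_f*V_f) / n``).

Parameters are estimated by progress-curve analysis — minimise the RMSE
between measured and simulated weekly *accumulated* quantities — in two
stages, mirroring the decoupling of the model (transpiration does not
depend on tank nutrient state, and each ion's uptake is independent of
the others given the volume trajectory):

1. canopy + transpiration parameters (a_lai, b_lai, x0, a_trs, b_trs)
   against accumulated per-plant transpiration;
2. per-ion Michaelis-Menten parameters (Jmax, Km) against accumulated
   per-plant uptake, with the stage-1 parameters frozen.

Root geometry (Rmax, K1, k1, r0) is taken as known (destructively
measured) rather than fitted: only the product P_RSA*Jmax is
identifiable from tank depletion data, so fitting both would trade one
against the other freely.

The optimiser is multi-start Nelder-Mead in log-parameter space
(positivity by construction), Latin-hypercube starts over the bounds,
deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .ions import IONS, N_IONS, nutrient_vector
from .model_core import (PlantParams, integrate_batch, leaf_area_index,
                         root_length, root_surface_area)

__all__ = [
    "MeasurementCampaign",
    "EstimationResult",
    "nw_absorption",
    "rmse",
    "simulate_campaign",
    "fit_params",
    "default_bounds",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MeasurementCampaign:
    """Weekly closed-tank depletion records for one species.

    Arrays are indexed by week; concentrations in mol m-3, volumes m3,
    times in hours since transplanting.
    """

    species: str
    n_plants: int
    v0: float
    t_start: np.ndarray          # (W,)
    t_end: np.ndarray            # (W,)
    c_init: np.ndarray           # (W, 6)
    c_final: np.ndarray          # (W, 6)
    v_init: np.ndarray           # (W,)
    v_final: np.ndarray          # (W,)

    def __post_init__(self):
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.t_end = np.asarray(self.t_end, dtype=float)
        self.c_init = np.asarray(self.c_init, dtype=float)
        self.c_final = np.asarray(self.c_final, dtype=float)
        self.v_init = np.asarray(self.v_init, dtype=float)
        self.v_final = np.asarray(self.v_final, dtype=float)
        w = len(self.t_start)
        if w < 2:
            raise ValueError("a campaign needs at least 2 weeks")
        if self.c_init.shape != (w, N_IONS) or self.c_final.shape != (w, N_IONS):
            raise ValueError("concentration arrays must be (weeks, 6)")
        if np.any(self.v_final > self.v_init + 1e-12):
            raise ValueError("final volume exceeds initial volume "
                             "(water only leaves by transpiration)")
        if np.any(self.c_init < 0) or np.any(self.c_final < 0):
            raise ValueError("concentrations must be >= 0")

    @property
    def n_weeks(self) -> int:
        return len(self.t_start)

    def weekly_transpiration_per_plant(self) -> np.ndarray:
        """(W,) m3 plant-1 per week from the volume drawdown."""
        return (self.v_init - self.v_final) / self.n_plants

    def weekly_uptake_per_plant(self) -> np.ndarray:
        """(W, 6) mol plant-1 per week by the N/W method."""
        return (self.c_init * self.v_init[:, None]
                - self.c_final * self.v_final[:, None]) / self.n_plants

    def accumulated_transpiration(self) -> np.ndarray:
        return np.cumsum(self.weekly_transpiration_per_plant())

    def accumulated_uptake(self) -> np.ndarray:
        return np.cumsum(self.weekly_uptake_per_plant(), axis=0)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "species": self.species,
            "week": np.arange(1, self.n_weeks + 1),
            "t_start_h": self.t_start, "t_end_h": self.t_end,
            "v_init_m3": self.v_init, "v_final_m3": self.v_final,
        }
        for i, ion in enumerate(IONS):
            data[f"c_init_{ion}_mol_m3"] = self.c_init[:, i]
            data[f"c_final_{ion}_mol_m3"] = self.c_final[:, i]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_plants: int, v0: float
                   ) -> "MeasurementCampaign":
        return cls(
            species=str(df["species"].iloc[0]),
            n_plants=n_plants, v0=v0,
            t_start=df["t_start_h"].to_numpy(),
            t_end=df["t_end_h"].to_numpy(),
            c_init=np.column_stack(
                [df[f"c_init_{ion}_mol_m3"] for ion in IONS]),
            c_final=np.column_stack(
                [df[f"c_final_{ion}_mol_m3"] for ion in IONS]),
            v_init=df["v_init_m3"].to_numpy(),
            v_final=df["v_final_m3"].to_numpy(),
        )


@dataclass
class EstimationResult:
    params: PlantParams
    rmse_transpiration: float
    rmse_uptake: np.ndarray              # (6,) mol plant-1
    km_flat: np.ndarray                  # (6,) bool, weak Km identifiability
    n_evals: int
    converged: bool
    seed: int
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# elementary operations


def nw_absorption(c_init, v_init: float, c_final, v_final: float,
                  n_plants: int) -> np.ndarray:
    """Per-plant absorption (mol) over one closed-tank period:
    (C_i*V_i - C_f*V_f) / n.  Negative entries (efflux or measurement
    noise) are allowed but the caller may flag them."""
    c_init = nutrient_vector(c_init)
    c_final = nutrient_vector(c_final)
    if n_plants < 1:
        raise ValueError("n_plants must be >= 1")
    return (c_init * v_init - c_final * v_final) / n_plants


def rmse(simulated, measured) -> float:
    """Root mean square error between two equal-length series."""
    sim = np.asarray(simulated, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if sim.shape != meas.shape:
        raise ValueError("series length mismatch")
    if sim.size == 0:
        raise ValueError("series must be non-empty")
    return float(np.sqrt(np.mean((sim - meas) ** 2)))


# ---------------------------------------------------------------------------
# forward simulation of a campaign


def simulate_campaign(params: PlantParams, campaign: MeasurementCampaign,
                      env, dt: float = 1.0) -> dict:
    """Run the weekly-replacement protocol forward under ``params``.

    Each week starts from the recorded initial composition and volume
    (fresh fill), integrates with no within-week dosing, and the tank is
    replaced at the week boundary.  Returns accumulated per-plant
    transpiration (W,) and uptake (W, 6) at week ends, plus final
    volumes/concentrations.
    """
    w = campaign.n_weeks
    acc_trs = np.zeros(w)
    acc_upt = np.zeros((w, N_IONS))
    v_final = np.zeros(w)
    c_final = np.zeros((w, N_IONS))
    cum_t, cum_u = 0.0, np.zeros(N_IONS)
    for i in range(w):
        horizon = campaign.t_end[i] - campaign.t_start[i]
        raw = integrate_batch(
            np.array([campaign.v_init[i]]),
            (campaign.v_init[i] * campaign.c_init[i])[None, :],
            params, env, horizon, dt, policy=None,
            t0=campaign.t_start[i])
        cum_t += raw["cum_transpiration"][0, -1]
        cum_u = cum_u + raw["cum_uptake"][0, -1]
        acc_trs[i] = cum_t
        acc_upt[i] = cum_u
        v_final[i] = raw["volume"][0, -1]
        c_final[i] = raw["mass"][0, -1] / max(raw["volume"][0, -1], 1e-12)
    return {"accumulated_transpiration": acc_trs,
            "accumulated_uptake": acc_upt,
            "v_final": v_final, "c_final": c_final}


# ---------------------------------------------------------------------------
# fast kernels for the fit objectives (same RK4 grid as integrate_batch)


def _half_grid(campaign: MeasurementCampaign, dt: float):
    """Per-week half-step time grids (RK4 samples every dt/2)."""
    grids = []
    for i in range(campaign.n_weeks):
        n = int(round((campaign.t_end[i] - campaign.t_start[i]) / dt))
        grids.append(campaign.t_start[i] + dt * 0.5 * np.arange(2 * n + 1))
    return grids


def _cum_transpiration_at_week_ends(theta, campaign, k_half, vpd_half,
                                    t_half, params: PlantParams,
                                    dt: float) -> np.ndarray:
    """Accumulated per-plant transpiration at week ends for stage-1
    parameters theta = (a_trs, b_trs, a_lai, b_lai, x0)."""
    a_trs, b_trs, a_lai, b_lai, x0 = theta
    out = np.zeros(campaign.n_weeks)
    cum = 0.0
    for i in range(campaign.n_weeks):
        lai = a_lai / (1.0 + np.exp((x0 - t_half[i]) / b_lai))
        q = (a_trs * (1.0 - np.exp(-params.k_ext * lai)) * k_half[i]
             + b_trs * lai * vpd_half[i])
        cum += dt / 6.0 * float(q[0:-1:2].sum() + 4 * q[1::2].sum()
                                + q[2::2].sum())
        out[i] = cum
    return out


def _deplete_ion(jmax: float, km: float, m0: np.ndarray, v_half: list,
                 prsa_half: list, n_plants: int, dt: float) -> np.ndarray:
    """Accumulated per-plant uptake of one ion at week ends.

    Scalar RK4 per week on dM/dt = -n * P_RSA(t) * Jmax * C/(Km + C),
    C = M/V, with V(t) precomputed on the half grid (stage-1 fit).
    """
    weeks = len(m0)
    out = np.zeros(weeks)
    cum = 0.0
    for w in range(weeks):
        m = float(m0[w])
        vh = v_half[w]
        ph = prsa_half[w]
        n_steps = (len(vh) - 1) // 2
        for s in range(n_steps):
            i0 = 2 * s
            def f(mm, idx):
                if mm <= 0.0:
                    return 0.0
                c = mm / vh[idx]
                return -n_plants * ph[idx] * jmax * c / (km + c)
            k1 = f(m, i0)
            k2 = f(m + dt * 0.5 * k1, i0 + 1)
            k3 = f(m + dt * 0.5 * k2, i0 + 1)
            k4 = f(m + dt * k3, i0 + 2)
            m += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            if m < 0.0:
                m = 0.0
        cum += (float(m0[w]) - m) / n_plants
        out[w] = cum
    return out


# ---------------------------------------------------------------------------
# fitting


def default_bounds() -> dict:
    """Broad positive search bounds for the fitted parameters.

    The Km ceiling (2 mol m-3) reflects transporter half-saturation for
    macronutrient uptake, which sits in the sub-mM to low-mM range;
    letting Km roam far above the observed concentrations would leave
    the Jmax/Km ridge unconstrained.
    """
    return {
        "a_trs": (1e-8, 5e-6), "b_trs": (5e-8, 3e-5),
        "a_lai": (0.5, 10.0), "b_lai": (40.0, 500.0), "x0": (150.0, 1200.0),
        "jmax": (1e-6, 5e-3), "km": (0.05, 2.0),
    }


def _lhs_starts(bounds_arr: np.ndarray, n_starts: int, seed: int
                ) -> np.ndarray:
    """Latin-hypercube starts in log space; first start is the log-midpoint."""
    lo, hi = np.log(bounds_arr[:, 0]), np.log(bounds_arr[:, 1])
    mid = 0.5 * (lo + hi)
    if n_starts == 1:
        return mid[None, :]
    sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
    u = sampler.random(n_starts - 1)
    return np.vstack([mid, lo + u * (hi - lo)])


def _multistart_nm(objective, bounds_arr: np.ndarray, n_starts: int,
                   seed: int, maxfev: int):
    """Multi-start Nelder-Mead on log-parameters clipped to bounds."""
    lo, hi = np.log(bounds_arr[:, 0]), np.log(bounds_arr[:, 1])

    def wrapped(logx):
        x = np.exp(np.clip(logx, lo, hi))
        penalty = float(np.sum(np.maximum(logx - hi, 0) ** 2
                               + np.maximum(lo - logx, 0) ** 2))
        return objective(x) * (1.0 + penalty) + penalty

    best, best_f, evals = None, np.inf, 0
    for start in _lhs_starts(bounds_arr, n_starts, seed):
        res = minimize(wrapped, start, method="Nelder-Mead",
                       options={"maxfev": maxfev, "fatol": 1e-12,
                                "xatol": 1e-8})
        evals += res.nfev
        if res.fun < best_f:
            best_f, best = res.fun, np.exp(np.clip(res.x, lo, hi))
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    return best, best_f, evals


def fit_params(campaign: MeasurementCampaign, env,
               base_params: PlantParams, *,
               bounds: dict | None = None,
               which: tuple[str, ...] = ("transpiration", "uptake"),
               seed: int = 0, n_starts: int = 6, n_starts_uptake: int = 3,
               dt: float = 1.0, maxfev: int = 600) -> EstimationResult:
    """Two-stage progress-curve fit against a weekly depletion campaign.

    ``base_params`` supplies the fixed root geometry (Rmax, K1, k1, r0),
    k_ext and n_plants; fitted fields are replaced in the returned
    params.  Deterministic for fixed ``seed``.
    """
    bounds = {**default_bounds(), **(bounds or {})}
    t_half = _half_grid(campaign, dt)
    k_half, vpd_half = zip(*(env.sample(g) for g in t_half))
    total_evals = 0
    params = base_params
    rmse_trs = float("nan")
    diagnostics: dict = {}

    meas_trs = campaign.accumulated_transpiration()
    if "transpiration" in which:
        names = ("a_trs", "b_trs", "a_lai", "b_lai", "x0")
        barr = np.array([bounds[n] for n in names])

        def obj_trs(x):
            sim = _cum_transpiration_at_week_ends(
                x, campaign, k_half, vpd_half, t_half, params, dt)
            return rmse(sim, meas_trs)

        best, best_f, ev = _multistart_nm(obj_trs, barr, n_starts, seed,
                                          maxfev)
        total_evals += ev
        params = params.with_(**dict(zip(names, best)))
        rmse_trs = best_f
        diagnostics["transpiration"] = {"rmse": best_f, "nfev": ev}

    # volume and root-surface trajectories implied by the stage-1 fit
    v_half, prsa_half = [], []
    for i, grid in enumerate(t_half):
        lai = leaf_area_index(grid, params)
        kk, vv = k_half[i], vpd_half[i]
        q = (params.a_trs * (1.0 - np.exp(-params.k_ext * lai)) * kk
             + params.b_trs * lai * vv)
        # cumulative per-plant transpiration on the half grid (trapezoid
        # at dt/2 resolution; consistent with RK4 to O(dt^2) in V only)
        cum = np.concatenate([[0.0], np.cumsum(
            0.25 * dt * (q[:-1] + q[1:]))])
        v_half.append(np.maximum(campaign.v_init[i]
                                 - params.n_plants * cum, 1e-9))
        prsa_half.append(root_surface_area(root_length(grid, params),
                                           params.r0))

    rmse_upt = np.full(N_IONS, np.nan)
    km_flat = np.zeros(N_IONS, dtype=bool)
    if "uptake" in which:
        meas_upt = campaign.accumulated_uptake()
        m0 = campaign.c_init * campaign.v_init[:, None]
        jmax_fit = params.jmax.copy()
        km_fit = params.km.copy()
        barr = np.array([bounds["jmax"], bounds["km"]])
        for ion in range(N_IONS):
            meas_i = meas_upt[:, ion]
            m0_i = m0[:, ion]

            def obj_ion(x, _m0=m0_i, _meas=meas_i):
                sim = _deplete_ion(x[0], x[1], _m0, v_half, prsa_half,
                                   params.n_plants, dt)
                return rmse(sim, _meas)

            best, best_f, ev = _multistart_nm(
                obj_ion, barr, n_starts_uptake, seed + 1000 + ion, maxfev)
            total_evals += ev
            jmax_fit[ion], km_fit[ion] = best
            rmse_upt[ion] = best_f
            # Km identifiability probe: double Km, rescale Jmax so the
            # initial-concentration uptake matches, and compare RMSE
            c_bar = float(np.mean(campaign.c_init[:, ion]))
            j_alt = best[0] * (2 * best[1] + c_bar) / (best[1] + c_bar)
            alt_f = obj_ion(np.array([j_alt, 2 * best[1]]))
            scale = max(best_f, 1e-3 * float(np.max(np.abs(meas_i))) + 1e-300)
            km_flat[ion] = (alt_f - best_f) / scale < 0.05
        params = params.with_(jmax=jmax_fit, km=km_fit)
        diagnostics["uptake"] = {"rmse": rmse_upt.tolist()}

    return EstimationResult(
        params=params, rmse_transpiration=rmse_trs, rmse_uptake=rmse_upt,
        km_flat=km_flat, n_evals=total_evals, converged=True, seed=seed,
        diagnostics=diagnostics)
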