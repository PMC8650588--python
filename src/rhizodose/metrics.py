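"""Ensemble reproducibility metrics, dosing-rate signatures, and the
end-to-end pipeline.

The reproducibility question is: if the weather (hence transpiration) is
stochastic, how spread out are the root-zone nutrient trajectories
across replicate runs under each dosing controller?  The headline
statistic is the percent coefficient of variation (%CV) of each ion's
concentration across replicates at each output time, averaged over time.
The volume-based controller couples nutrient input to the stochastic
water draw, so it spreads; the time- and EC+volume-based controllers
decouple input from weather and stay tight.

Also here: trend statistics that classify each controller's dose-event
series (irregular / constant / increasing), the waste (emission) ledger,
and ``run_pipeline`` chaining data generation, fitting, the dosing
comparison, and composition optimization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from .dosing import DosingPolicy, calibrate_time_dose
from .environment import EnvironmentSchedule, stochastic_weather_trajectory
from .estimation import fit_params
from .ions import IONS, VALENCES, nutrient_vector
from .model_core import PlantParams, integrate_batch
from .optimization import (STEINER_RATIO, Scenario, composition_to_ratio,
                           jmax_ratio_cv, optimize_dosing_composition)
from .synthetic_data import (STEINER_MEAN_MOL_M3, SyntheticSpec,
                             generate_campaign, sample_ground_truth,
                             species_preset)

__all__ = [
    "EnsembleSummary",
    "percent_cv",
    "compare_dosing",
    "make_matched_policies",
    "dosing_rate_signature",
    "replacement_waste",
    "run_pipeline",
]


def percent_cv(values, axis: int = 0) -> np.ndarray | float:
    """%CV = 100 * sample sd / mean across replicates (ddof=1)."""
    arr = np.asarray(values, dtype=float)
    if arr.shape[axis] < 2:
        raise ValueError("need at least 2 replicates")
    mean = arr.mean(axis=axis)
    if np.any(mean == 0):
        raise ValueError("%CV undefined for zero mean")
    out = 100.0 * arr.std(axis=axis, ddof=1) / mean
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class EnsembleSummary:
    """Dosing-method comparison over a common set of weather replicates."""

    methods: tuple[str, ...]
    t: np.ndarray                                  # (n+1,)
    cv_by_ion: dict[str, np.ndarray]               # method -> (6,) time-mean %CV
    cv_mean: dict[str, float]                      # method -> scalar
    cv_over_time: dict[str, np.ndarray]            # method -> (n_times, 6)
    dose_times: dict[str, np.ndarray]
    dose_equivalents: dict[str, np.ndarray]        # method -> (replicates, events) eq
    conc_quantiles: dict[str, np.ndarray]          # method -> (3, n+1, 6): q10/50/90
    waste_water: float = 0.0                       # m3 discarded (0 for all controllers)
    waste_nutrients: np.ndarray = field(
        default_factory=lambda: np.zeros(len(IONS)))
    seeds: tuple[int, ...] = ()


def make_matched_policies(params: PlantParams,
                          schedule: EnvironmentSchedule, *,
                          v0: float = 0.3,
                          feed=STEINER_MEAN_MOL_M3,
                          interval: float = 24.0,
                          horizon: float = 1296.0, dt: float = 0.5,
                          calibration_seed: int = 987654,
                          ) -> dict[str, DosingPolicy]:
    """The three controllers with input-matched settings.

    The shared feed is the standard composition; EC0 is its total
    equivalents; the time controller's fixed dose is calibrated so its
    cumulative input over the horizon matches an EC+volume reference run
    under one stochastic weather draw.
    """
    feed = nutrient_vector(feed)
    ec0 = float(feed @ VALENCES)
    base = DosingPolicy(kind="ec_volume", interval=interval, feed=feed,
                        v0=v0, ec0=ec0)
    ref_env = stochastic_weather_trajectory(schedule, horizon, dt,
                                            seed=calibration_seed)
    time_policy = calibrate_time_dose(params, ref_env, base,
                                      horizon=horizon, dt=dt)
    return {"volume": base.with_(kind="volume"),
            "time": time_policy,
            "ec_volume": base}


def compare_dosing(params: PlantParams,
                   policies: dict[str, DosingPolicy],
                   n_replicates: int = 50, seed: int = 0, *,
                   schedule: EnvironmentSchedule | None = None,
                   initial=STEINER_MEAN_MOL_M3,
                   horizon: float = 1296.0, dt: float = 0.5
                   ) -> EnsembleSummary:
    """Run every policy over the same ``n_replicates`` stochastic weather
    seeds and summarise the across-replicate %CV of each ion.

    %CV is computed across replicates at each output time and then
    averaged over time (t=0 excluded: all replicates start identical).
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if schedule is None:
        schedule = EnvironmentSchedule(mode="stochastic")
    initial = nutrient_vector(initial)
    seeds = tuple(seed + i for i in range(n_replicates))

    n = int(round(horizon / dt))
    t_half = dt * 0.5 * np.arange(2 * n + 1)
    k_rows, v_rows = [], []
    for s in seeds:
        wt = stochastic_weather_trajectory(schedule, horizon, dt, seed=s)
        k, v = wt.sample(t_half)
        k_rows.append(k)
        v_rows.append(v)

    class _Stacked:
        def sample(self, times):
            del times
            return np.array(k_rows), np.array(v_rows)

    env = _Stacked()
    v0s = {name: pol.v0 for name, pol in policies.items()}

    cv_by_ion, cv_mean, cv_over_time = {}, {}, {}
    dose_times, dose_eq, quantiles = {}, {}, {}
    t_out = None
    for name, policy in policies.items():
        b = n_replicates
        v0 = np.full(b, v0s[name])
        m0 = np.tile(v0s[name] * initial, (b, 1))
        raw = integrate_batch(v0, m0, params, env, horizon, dt,
                              policy=policy)
        t_out = raw["t"]
        conc = raw["mass"] / np.maximum(raw["volume"], 1e-12)[:, :, None]
        cv_t = percent_cv(conc[:, 1:, :], axis=0)      # (n_times, 6)
        cv_over_time[name] = cv_t
        cv_by_ion[name] = cv_t.mean(axis=0)
        cv_mean[name] = float(cv_t.mean())
        dose_times[name] = raw["dose_times"]
        dose_eq[name] = raw["dose_nutrients"] @ VALENCES
        quantiles[name] = np.quantile(conc, [0.1, 0.5, 0.9], axis=0)

    return EnsembleSummary(
        methods=tuple(policies), t=t_out, cv_by_ion=cv_by_ion,
        cv_mean=cv_mean, cv_over_time=cv_over_time,
        dose_times=dose_times, dose_equivalents=dose_eq,
        conc_quantiles=quantiles, seeds=seeds)


def dosing_rate_signature(dose_equivalents: np.ndarray, *,
                          constant_cv: float = 1.0,
                          trend_tau: float = 0.5) -> dict:
    """Classify a dose-event series as constant / increasing / irregular.

    Statistics: %CV of the series; Kendall's tau against event order
    (monotone trend); and the *noise-to-trend ratio* — the standard
    deviation of event-to-event increments over the mean increment.
    A weather-tracking series is jagged (increments fluctuate more than
    they trend, ratio > 1) even when it also rises with plant growth; a
    growth-tracking series is smooth (ratio < 1).  A series is
    *constant* if %CV < ``constant_cv``; else *increasing* if tau >
    ``trend_tau`` and the noise-to-trend ratio is below 1; otherwise
    *irregular*.
    """
    s = np.asarray(dose_equivalents, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 dose events")
    cv = 100.0 * s.std(ddof=1) / s.mean() if s.mean() != 0 else np.inf
    tau, _ = kendalltau(np.arange(s.size), s)
    tau = 0.0 if np.isnan(tau) else float(tau)
    diffs = np.diff(s)
    mean_inc = diffs.mean()
    noise_to_trend = (float(diffs.std(ddof=1) / abs(mean_inc))
                      if mean_inc != 0 else np.inf)
    if cv < constant_cv:
        label = "constant"
    elif tau > trend_tau and noise_to_trend < 1.0:
        label = "increasing"
    else:
        label = "irregular"
    return {"label": label, "cv_percent": float(cv), "kendall_tau": tau,
            "noise_to_trend": float(noise_to_trend)}


def replacement_waste(campaign) -> dict:
    """Emission ledger of the weekly-replacement protocol: everything in
    the tank at each week end is discarded."""
    water = float(campaign.v_final.sum())
    nutrients = (campaign.c_final * campaign.v_final[:, None]).sum(axis=0)
    return {"water_m3": water, "nutrients_mol": nutrients}


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: dict, seed: int, outdir: str | Path) -> dict:
    """generate-data -> fit -> compare-dosing -> optimize, with artifacts.

    ``config`` keys (all optional): ``weeks``, ``n_replicates``,
    ``opt_seeds``, ``opt_horizon``, ``dt``, ``species``, ``fit_starts``,
    ``opt_maxfev``.  Returns the report dict also written to
    ``report.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    weeks = int(config.get("weeks", 8))
    n_rep = int(config.get("n_replicates", 50))
    dt = float(config.get("dt", 0.5))
    species = config.get("species", ("pakchoi", "lacinato", "curly"))

    # 1. synthetic campaigns
    spec = SyntheticSpec(species=tuple(species), weeks=weeks)
    truth_params = sample_ground_truth(spec, seed)
    campaigns = {}
    for i, (name, pars) in enumerate(truth_params.items()):
        noisy, _ = generate_campaign(pars, spec, seed + 17 * i)
        campaigns[name] = noisy
        noisy.to_frame().to_csv(outdir / f"campaign_{name}.csv", index=False)

    # 2. progress-curve fits
    from .environment import controlled_room_trajectory
    env = controlled_room_trajectory(spec.schedule, spec.week_hours, spec.dt)
    fits = {}
    for name, camp in campaigns.items():
        base = species_preset(name, spec.n_plants)
        res = fit_params(camp, env, base, seed=seed,
                         n_starts=int(config.get("fit_starts", 4)),
                         maxfev=int(config.get("fit_maxfev", 600)))
        fits[name] = res
        with open(outdir / f"fit_{name}.json", "w") as fh:
            json.dump({
                "jmax_mol_m2_h": res.params.jmax.tolist(),
                "km_mol_m3": res.params.km.tolist(),
                "a_trs": res.params.a_trs, "b_trs": res.params.b_trs,
                "a_lai": res.params.a_lai, "b_lai": res.params.b_lai,
                "x0_h": res.params.x0,
                "rmse_transpiration_m3_plant": res.rmse_transpiration,
                "rmse_uptake_mol_plant": res.rmse_uptake.tolist(),
                "km_flat": res.km_flat.tolist(),
            }, fh, indent=2)

    # 3. dosing comparison with the fitted flagship (highest-capacity) species
    flagship = fits[species[0]].params
    schedule = EnvironmentSchedule(mode="stochastic")
    horizon = weeks * spec.week_hours
    policies = make_matched_policies(flagship, schedule, horizon=horizon,
                                     dt=dt)
    summary = compare_dosing(flagship, policies, n_replicates=n_rep,
                             seed=seed, schedule=schedule,
                             horizon=horizon, dt=dt)
    pd.DataFrame({"method": list(summary.cv_mean),
                  "cv_mean_percent": list(summary.cv_mean.values())}
                 ).to_csv(outdir / "dosing_cv.csv", index=False)

    # 4. composition optimization
    standard = composition_to_ratio(spec.composition_mean)
    scenario = Scenario(
        params=flagship, schedule=schedule,
        horizon=float(config.get("opt_horizon", horizon)), dt=dt,
        seeds=tuple(seed + j for j in range(int(config.get("opt_seeds", 3)))))
    opt = optimize_dosing_composition(standard, scenario, seed=seed,
                                      maxfev=int(config.get("opt_maxfev", 60)))

    stoich = jmax_ratio_cv([f.params for f in fits.values()])
    report = {
        "seed": seed,
        "species": list(species),
        "fit_rmse_transpiration": {k: fits[k].rmse_transpiration
                                   for k in fits},
        "dosing_cv_mean_percent": summary.cv_mean,
        "dosing_signatures": {
            m: dosing_rate_signature(summary.dose_equivalents[m][0])
            for m in summary.methods},
        "optimization": {
            "objective_standard": opt.objective_baseline,
            "objective_optimized": opt.objective_optimal,
            "optimal_ratio": opt.optimal_ratio.as_dict(),
            "standard_ratio": standard.as_dict(),
        },
        "jmax_stoichiometry": {
            "mean_jmax_cv_percent": stoich["mean_jmax_cv_percent"],
            "mean_ratio_cv_percent": stoich["mean_ratio_cv_percent"],
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
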