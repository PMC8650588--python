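"""Synthetic ground truth and measurement campaigns.

The raw depletion measurements behind the three-species growth-room
experiment are not deposited, so this module generates statistically
matched stand-ins: three *Brassica*-like parameter presets ordered
pakchoi > lacinato kale > curly kale in uptake and transpiration
capacity (with sulfate the exception — higher in the kales), and weekly
closed-tank campaigns over a 0.3 m3 tank with 84 plants, fresh fills
scattered around the Steiner-proportioned composition
(7.5, 3.0, 2.5, 4.0, 1.9, 1.4 mM of NO3, H2PO4, SO4, K, Ca, Mg;
26.1 meq L-1 total), and multiplicative measurement noise at
ion-chromatography/ICP-grade levels (3% per assay on concentrations,
each record the mean of 3 repeated assays as in the analytical
protocol; 1% on volumes).

Everything is seeded; the generator is the study-conditions oracle the
estimation and optimization tests recover against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .environment import EnvironmentSchedule, controlled_room_trajectory
from .estimation import MeasurementCampaign
from .ions import N_IONS, nutrient_vector
from .model_core import PlantParams, integrate_batch

__all__ = [
    "SyntheticSpec",
    "STEINER_MEAN_MOL_M3",
    "STEINER_SD_MOL_M3",
    "species_preset",
    "sample_ground_truth",
    "sample_initial_composition",
    "generate_campaign",
]

#: Fresh-fill composition means (mol m-3) for (NO3, H2PO4, SO4, K, Ca, Mg);
#: totals 26.1 eq m-3 on the equivalent scale.
STEINER_MEAN_MOL_M3 = np.array([7.5, 3.0, 2.5, 4.0, 1.9, 1.4])
#: Week-to-week scatter of the fresh fills (mol m-3).
STEINER_SD_MOL_M3 = np.array([1.0, 1.4, 1.1, 0.4, 0.4, 0.2])

_PRESET_NAMES = ("pakchoi", "lacinato", "curly")

# Species capacity scaling pakchoi > lacinato > curly, applied to Jmax and
# the transpiration coefficients; SO4 uptake is set separately (kales
# absorb distinctly more sulfate than pakchoi).
_CAPACITY = {"pakchoi": 1.0, "lacinato": 0.80, "curly": 0.65}
_JMAX_PAKCHOI = np.array([6.0e-4, 0.60e-4, 1.40e-4, 3.2e-4, 1.30e-4, 0.90e-4])
_JMAX_SO4 = {"pakchoi": 1.40e-4, "lacinato": 2.10e-4, "curly": 1.90e-4}
_KM = np.array([0.5, 0.2, 0.3, 0.4, 0.3, 0.25])
_ROOT = {"pakchoi": dict(rmax=120.0, a_lai=3.0),
         "lacinato": dict(rmax=100.0, a_lai=2.6),
         "curly": dict(rmax=85.0, a_lai=2.2)}


def species_preset(name: str, n_plants: int = 84) -> PlantParams:
    """Named synthetic parameter preset ('pakchoi' | 'lacinato' | 'curly').

    Magnitudes are chosen so that weekly per-plant transpiration sits in
    the 1e-4..1e-3 m3 range and late-season weekly tank depletion is a
    clearly measurable 10-40% of the fill per ion, as in a depletion
    experiment designed to resolve uptake — synthetic values, not
    fitted ones.
    """
    key = name.lower().split("-")[0]
    if key not in _PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; use one of {_PRESET_NAMES}")
    s = _CAPACITY[key]
    jmax = _JMAX_PAKCHOI * s
    jmax[2] = _JMAX_SO4[key]
    return PlantParams(
        jmax=jmax, km=_KM.copy(),
        rmax=_ROOT[key]["rmax"], K1=30.0, k1=0.005, r0=1.5e-4,
        a_lai=_ROOT[key]["a_lai"], b_lai=160.0, x0=648.0,
        a_trs=2.0e-7 * s, b_trs=1.2e-6 * s, k_ext=0.7,
        n_plants=n_plants)


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of the synthetic experiment.

    Defaults reproduce the study conditions: 84 plants per species in a
    0.3 m3 tank, 8 weekly fills covering the ~54-day cultivation, fresh
    fills scattered around the Steiner-proportioned means.
    """

    species: tuple[str, ...] = _PRESET_NAMES
    n_plants: int = 84
    v0: float = 0.3
    weeks: int = 8
    week_hours: float = 168.0
    conc_noise_rel: float = 0.03
    volume_noise_rel: float = 0.01
    n_assays: int = 3
    composition_mean: np.ndarray = field(
        default_factory=lambda: STEINER_MEAN_MOL_M3.copy())
    composition_sd: np.ndarray = field(
        default_factory=lambda: STEINER_SD_MOL_M3.copy())
    jmax_jitter_rel: float = 0.10
    schedule: EnvironmentSchedule = field(
        default_factory=EnvironmentSchedule)
    dt: float = 1.0

    def __post_init__(self):
        if self.weeks < 2:
            raise ValueError("at least 2 weeks required")
        if self.conc_noise_rel < 0 or self.volume_noise_rel < 0:
            raise ValueError("noise levels must be >= 0")
        if self.n_assays < 1:
            raise ValueError("n_assays must be >= 1")
        object.__setattr__(self, "composition_mean",
                           nutrient_vector(self.composition_mean))
        object.__setattr__(self, "composition_sd",
                           nutrient_vector(self.composition_sd))

    def with_(self, **kw) -> "SyntheticSpec":
        return replace(self, **kw)


def sample_ground_truth(spec: SyntheticSpec, seed: int
                        ) -> dict[str, PlantParams]:
    """Per-species ground-truth parameters: the named presets with a
    seeded log-normal jitter on Jmax (capacity ordering preserved by
    construction of the preset scales)."""
    rng = np.random.default_rng(seed)
    out = {}
    for name in spec.species:
        p = species_preset(name, spec.n_plants)
        if spec.jmax_jitter_rel > 0:
            jitter = rng.lognormal(0.0, spec.jmax_jitter_rel, N_IONS)
            # keep the cross-species ordering intact: jitter shrinks
            # towards 1 by half so presets never cross at default levels
            p = p.with_(jmax=p.jmax * (1.0 + (jitter - 1.0) * 0.5))
        out[name] = p
    return out


def sample_initial_composition(spec: SyntheticSpec,
                               rng: np.random.Generator) -> np.ndarray:
    """One fresh-fill composition: Gaussian scatter around the Steiner-
    proportioned means, floored at 5% of the mean to stay physical."""
    c = rng.normal(spec.composition_mean, spec.composition_sd)
    return np.maximum(c, 0.05 * spec.composition_mean)


def generate_campaign(params: PlantParams, spec: SyntheticSpec, seed: int
                      ) -> tuple[MeasurementCampaign, MeasurementCampaign]:
    """Simulate the weekly-replacement protocol and return
    (noisy campaign, noise-free truth campaign).

    Each week: fresh fill at a sampled composition, one week of closed-
    tank depletion under the controlled-room schedule (no within-week
    dosing), record initial and final (C, V), replace.  The noisy record
    perturbs concentrations and volumes multiplicatively.
    """
    rng = np.random.default_rng(seed)
    env = controlled_room_trajectory(spec.schedule, spec.week_hours, spec.dt)
    w = spec.weeks
    t_start = spec.week_hours * np.arange(w)
    t_end = t_start + spec.week_hours
    c_init = np.zeros((w, N_IONS))
    c_final = np.zeros((w, N_IONS))
    v_init = np.zeros(w)
    v_final = np.zeros(w)
    for i in range(w):
        comp = sample_initial_composition(spec, rng)
        raw = integrate_batch(np.array([spec.v0]),
                              (spec.v0 * comp)[None, :], params, env,
                              spec.week_hours, spec.dt, t0=t_start[i])
        c_init[i] = comp
        v_init[i] = spec.v0
        v_final[i] = raw["volume"][0, -1]
        c_final[i] = raw["mass"][0, -1] / max(v_final[i], 1e-12)

    truth = MeasurementCampaign(
        species="truth", n_plants=spec.n_plants, v0=spec.v0,
        t_start=t_start, t_end=t_end, c_init=c_init, c_final=c_final,
        v_init=v_init, v_final=v_final)

    # each recorded concentration is the mean of n_assays repeated
    # analyses, each with conc_noise_rel relative error
    shape_i = (spec.n_assays,) + c_init.shape
    cn_i = c_init * rng.normal(1.0, spec.conc_noise_rel, shape_i).mean(axis=0)
    cn_f = c_final * rng.normal(1.0, spec.conc_noise_rel, shape_i).mean(axis=0)
    vn_i = v_init * rng.normal(1.0, spec.volume_noise_rel, w)
    vn_f = v_final * rng.normal(1.0, spec.volume_noise_rel, w)
    # the measured drawdown keeps its sign (water only leaves the tank)
    vn_f = np.minimum(vn_f, vn_i)
    noisy = MeasurementCampaign(
        species="synthetic", n_plants=spec.n_plants, v0=spec.v0,
        t_start=t_start, t_end=t_end,
        c_init=np.maximum(cn_i, 0.0), c_final=np.maximum(cn_f, 0.0),
        v_init=vn_i, v_final=vn_f)
    return noisy, truth
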