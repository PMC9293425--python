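"""Synthetic geothermal-gradient study generator.

Generates a complete in-silico replica of the field study design so
every downstream stage (rates, fitting, statistics) can be exercised
and validated without any external data:

1. **Design** — a full factorial of transect replicates × distances
   from the heat source × biomes × depths (3 × 3 × 2 × 2 = 36 sampling
   points by default), each incubated at 22 temperatures (4–46 °C in
   2 °C steps).
2. **Environment** — mean environmental temperature (MET) anchored on
   the published cell means and decreasing with distance from the heat
   source; pH negatively coupled to MET; soil carbon lognormal with
   biome×depth medians; N derived from C via biome-level C:N; water
   content independent.
3. **Traits** — each point receives true MMRT parameters built by
   inverting a trait triple: T_opt linear in C (default slope
   1.3 °C %C⁻¹) and MET (default slope 0 — the field study's null
   result), ΔCP‡ uniform over the published range, ln R25 linear in C.
4. **Incubations** — vial readings whose ppm increase is the exact
   inverse of the rate computation, with multiplicative lognormal
   rate noise, Gaussian temperature-control jitter and ambient initial
   CO2; durations clipped to the protocol's 52–169 min window.

One global seed drives a hierarchical stream (environment → traits →
incubations → dead-sample choice), so repeated runs are byte-for-byte
identical and sub-stages are reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import datasets
from .constants import DEFAULT_CONSTANTS, ThermoConstants, celsius_to_kelvin
from .respiration import (
    DEFAULT_SOIL_DENSITY,
    DEFAULT_VIAL_VOLUME_ML,
    default_headspace_volume,
    mass_for_temperature,
)
from .thermo import MMRTParams, invert_traits, mmrt_log_rate, t_inf

__all__ = [
    "DesignSpec",
    "EnvironmentModel",
    "TraitModel",
    "IncubationProtocol",
    "generate_design",
    "generate_environment",
    "assign_true_params",
    "simulate_incubations",
    "inject_dead_sample",
    "simulate_study",
]


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design: transects × distances × biomes × depths."""

    n_transects: int = 3
    distances_m: tuple[int, ...] = (2, 10, 30)
    biomes: tuple[str, ...] = ("grassland", "kanuka")
    depths: tuple[str, ...] = ("0-50 mm", "50-100 mm")
    incubation_temps_C: tuple[float, ...] = tuple(float(t) for t in range(4, 47, 2))

    def __post_init__(self) -> None:
        if self.n_transects < 1 or not (self.distances_m and self.biomes and self.depths):
            raise ValueError("all design factors must be non-empty")
        temps = np.asarray(self.incubation_temps_C)
        if temps.size == 0 or np.any(np.diff(temps) <= 0):
            raise ValueError("incubation temperatures must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.n_transects * len(self.distances_m) * len(self.biomes) * len(self.depths)


def _default_met_anchors() -> dict[tuple[str, str, int], float]:
    env = datasets.environment_summary()
    return {
        (r.biome, r.depth, int(r.distance_m)): float(r.MET_C) for r in env.itertuples()
    }


def _default_c_medians() -> dict[tuple[str, str], float]:
    # geometric-scale medians per biome × depth, bracketing the
    # published cell means
    return {
        ("grassland", "0-50 mm"): 10.5,
        ("grassland", "50-100 mm"): 4.3,
        ("kanuka", "0-50 mm"): 15.0,
        ("kanuka", "50-100 mm"): 4.5,
    }


@dataclass
class EnvironmentModel:
    """Covariate model for the sampling points.

    MET is anchored per biome × depth × distance on the published cell
    means; each transect × biome × depth combination receives a shared
    offset (``met_transect_sd``) plus small within-cell noise, so MET
    always decreases with distance within a transect.  pH follows MET
    with a negative slope; C is lognormal; N = C / (biome C:N);
    volumetric water content is independent uniform.  Generated values
    are clipped to the envelope of the published cell means.
    """

    met_anchors_C: dict[tuple[str, str, int], float] = field(default_factory=_default_met_anchors)
    met_transect_sd: float = 2.0
    met_within_sd: float = 0.5
    met_range_C: tuple[float, float] = (16.9, 48.3)
    ph_intercepts: dict[str, float] = field(
        default_factory=lambda: {"grassland": 5.3, "kanuka": 4.3}
    )
    ph_met_slope: float = -0.03  # pH per °C, negative
    ph_sd: float = 0.15
    ph_range: tuple[float, float] = (3.1, 4.9)
    c_log_medians: dict[tuple[str, str], float] = field(default_factory=_default_c_medians)
    c_log_sd: float = 0.35
    c_range_pct: tuple[float, float] = (1.2, 32.3)
    cn_means: dict[str, float] = field(
        default_factory=lambda: {"grassland": 13.7, "kanuka": 21.8}
    )
    cn_sds: dict[str, float] = field(
        default_factory=lambda: {"grassland": 1.0, "kanuka": 2.5}
    )
    cn_range: tuple[float, float] = (12.3, 27.0)
    n_range_pct: tuple[float, float] = (0.07, 1.45)
    ws_range: tuple[float, float] = (0.20, 0.42)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.met_anchors_C.values()):
            raise ValueError("MET anchors must be positive (°C)")
        if self.ph_met_slope > 0:
            raise ValueError("pH–MET slope must not be positive")
        for name in ("met_transect_sd", "met_within_sd", "ph_sd", "c_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TraitModel:
    """Environment → true MMRT trait links for the generator.

    T_opt (°C) = intercept + C-slope·C + MET-slope·MET + noise;
    ΔCP‡ uniform over ``dcp_range``; ln R25 = intercept + slope·C +
    noise.  The default MET slope of zero encodes the field study's
    null result (thermal history does not shift the traits); the C
    slope of 1.3 °C %C⁻¹ is the published substrate effect.
    ``rate_log_sd`` is the lognormal measurement noise applied to each
    incubation's rate.
    """

    topt_intercept_C: float = 51.0
    topt_C_slope: float = 1.3  # °C per % C
    topt_MET_slope: float = 0.0  # °C per °C
    topt_sd: float = 8.0
    dcp_range: tuple[float, float] = (-3400.0, -1100.0)  # J mol⁻¹ K⁻¹
    lnr25_intercept: float = 1.4
    lnr25_C_slope: float = 0.08  # per % C
    lnr25_sd: float = 0.3
    rate_log_sd: float = 0.15
    max_retries: int = 100

    def __post_init__(self) -> None:
        lo, hi = self.dcp_range
        if not (lo <= hi and hi < -DEFAULT_CONSTANTS.R_gas):
            raise ValueError("dcp_range must lie below -R_gas")
        for name in ("topt_sd", "lnr25_sd", "rate_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class IncubationProtocol:
    """Vial protocol emulated by the incubation simulator."""

    vial_volume_ml: float = DEFAULT_VIAL_VOLUME_ML
    soil_density: float = DEFAULT_SOIL_DENSITY
    temp_sd_C: float = 0.25  # ±0.5 °C box control
    initial_ppm_mean: float = 410.0
    initial_ppm_sd: float = 10.0
    target_delta_ppm: float = 550.0
    duration_bounds_min: tuple[float, float] = (52.0, 169.0)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_design(spec: DesignSpec = DesignSpec()) -> pd.DataFrame:
    """Enumerate the factorial design (one row per sampling point)."""
    rows = []
    for biome in spec.biomes:
        for transect in range(1, spec.n_transects + 1):
            for depth in spec.depths:
                for dist in spec.distances_m:
                    depth_tag = depth.replace(" mm", "").replace(" ", "")
                    rows.append(
                        {
                            "point_id": f"{biome}-T{transect}-{dist}m-{depth_tag}",
                            "transect": f"{biome[:1].upper()}{transect}",
                            "biome": biome,
                            "depth": depth,
                            "distance_m": int(dist),
                        }
                    )
    return pd.DataFrame(rows)


def generate_environment(
    design: pd.DataFrame,
    model: EnvironmentModel = None,
    seed=0,
) -> pd.DataFrame:
    """Attach environment covariates (MET, Ws, pH, C, N, C:N) to the design."""
    model = model or EnvironmentModel()
    rng = _as_rng(seed)
    df = design.copy().reset_index(drop=True)

    # shared transect offsets keep MET monotone in distance within a
    # transect × biome × depth series
    combos = sorted(set(zip(df["transect"], df["biome"], df["depth"])))
    offsets = {combo: rng.normal(0.0, model.met_transect_sd) for combo in combos}

    met = np.empty(len(df))
    for i, row in df.iterrows():
        anchor = model.met_anchors_C.get((row["biome"], row["depth"], int(row["distance_m"])))
        if anchor is None:
            raise ValueError(
                f"no MET anchor for ({row['biome']}, {row['depth']}, {row['distance_m']})"
            )
        met[i] = anchor + offsets[(row["transect"], row["biome"], row["depth"])] + rng.normal(
            0.0, model.met_within_sd
        )
    met = np.clip(met, *model.met_range_C)
    df["MET_C"] = met

    df["Ws_m3m3"] = rng.uniform(*model.ws_range, size=len(df))

    ph = (
        df["biome"].map(model.ph_intercepts).to_numpy(dtype=float)
        + model.ph_met_slope * met
        + rng.normal(0.0, model.ph_sd, size=len(df))
    )
    df["pH"] = np.clip(ph, *model.ph_range)

    medians = np.array(
        [model.c_log_medians[(b, d)] for b, d in zip(df["biome"], df["depth"])]
    )
    c = medians * np.exp(rng.normal(0.0, model.c_log_sd, size=len(df)))
    c = np.clip(c, *model.c_range_pct)
    df["C_pct"] = c

    cn = np.array(
        [
            rng.normal(model.cn_means[b], model.cn_sds[b])
            for b in df["biome"]
        ]
    )
    cn = np.clip(cn, *model.cn_range)
    n = np.clip(c / cn, *model.n_range_pct)
    df["N_pct"] = n
    df["CN"] = c / n
    return df


def assign_true_params(
    points: pd.DataFrame,
    model: TraitModel = None,
    seed=0,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Draw true MMRT parameters for every point via trait inversion.

    Adds ``true_*`` columns (SI parameters plus the drawn traits in
    reporting units).  Draws violating the trait→parameter
    preconditions are redrawn up to ``max_retries`` times.
    """
    model = model or TraitModel()
    rng = _as_rng(seed)
    df = points.copy().reset_index(drop=True)
    cols = {name: np.empty(len(df)) for name in (
        "true_dH0_J_mol", "true_dCp_J_mol_K", "true_dS0_J_mol_K",
        "true_T_opt_C", "true_T_inf_C", "true_R25_umol_g_min",
    )}
    for i, row in df.iterrows():
        params = None
        for _ in range(model.max_retries):
            topt_c = (
                model.topt_intercept_C
                + model.topt_C_slope * row["C_pct"]
                + model.topt_MET_slope * row["MET_C"]
                + rng.normal(0.0, model.topt_sd)
            )
            dcp = rng.uniform(*model.dcp_range)
            r25_val = np.exp(
                model.lnr25_intercept
                + model.lnr25_C_slope * row["C_pct"]
                + rng.normal(0.0, model.lnr25_sd)
            )
            try:
                params = invert_traits(celsius_to_kelvin(topt_c), dcp, r25_val, consts)
                break
            except ValueError:
                continue
        if params is None:
            raise RuntimeError(f"could not draw valid traits for point {row['point_id']}")
        cols["true_dH0_J_mol"][i] = params.dH0
        cols["true_dCp_J_mol_K"][i] = params.dCp
        cols["true_dS0_J_mol_K"][i] = params.dS0
        cols["true_T_opt_C"][i] = topt_c
        cols["true_T_inf_C"][i] = t_inf(params, consts) - 273.15
        cols["true_R25_umol_g_min"][i] = r25_val
    for name, arr in cols.items():
        df[name] = arr
    return df


def _true_params(row) -> MMRTParams:
    return MMRTParams(
        dH0=float(row["true_dH0_J_mol"]),
        dCp=float(row["true_dCp_J_mol_K"]),
        dS0=float(row["true_dS0_J_mol_K"]),
    )


def simulate_incubations(
    points: pd.DataFrame,
    spec: DesignSpec = DesignSpec(),
    protocol: IncubationProtocol = None,
    rate_log_sd: float = 0.15,
    seed=0,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Simulate vial readings for every point × incubation temperature.

    The final ppm is computed as the exact inverse of the rate
    calculation in :mod:`thermoresp.respiration`, so with all noise
    scales at zero the pipeline recovers the true rates exactly.
    Durations are chosen to target a fixed headspace ppm increase and
    clipped to the protocol window.
    """
    protocol = protocol or IncubationProtocol()
    rng = _as_rng(seed)
    lo_dur, hi_dur = protocol.duration_bounds_min
    rows = []
    for _, row in points.iterrows():
        params = _true_params(row)
        for target in spec.incubation_temps_C:
            measured = target + rng.normal(0.0, protocol.temp_sd_C)
            mass = mass_for_temperature(target)
            log_rate = mmrt_log_rate(params, celsius_to_kelvin(measured), consts)
            rate = np.exp(log_rate + rng.normal(0.0, rate_log_sd))
            initial = rng.normal(protocol.initial_ppm_mean, protocol.initial_ppm_sd)
            headspace = default_headspace_volume(
                protocol.vial_volume_ml, mass, protocol.soil_density
            )
            # moles of headspace gas at the incubation temperature
            n_gas = consts.P_atm * headspace * 1e-6 / (
                consts.R_gas * celsius_to_kelvin(measured)
            )
            # ppm increase per minute at this rate; rate µmol g⁻¹ min⁻¹
            dppm_per_min = rate * mass / n_gas
            duration = float(np.clip(protocol.target_delta_ppm / dppm_per_min, lo_dur, hi_dur))
            final = initial + dppm_per_min * duration
            rows.append(
                {
                    "sample_id": row["point_id"],
                    "target_T_C": float(target),
                    "measured_T_C": float(measured),
                    "soil_dry_mass_g": mass,
                    "vial_volume_ml": protocol.vial_volume_ml,
                    "headspace_volume_ml": headspace,
                    "initial_ppm": float(initial),
                    "final_ppm": float(final),
                    "duration_min": duration,
                }
            )
    return pd.DataFrame(rows)


def inject_dead_sample(
    incubations: pd.DataFrame,
    sample_id: str | None = None,
    seed=0,
    biome_tag: str = "kanuka",
) -> tuple[pd.DataFrame, str]:
    """Silence one sample: its final ppm equals its initial ppm everywhere.

    Emulates the one field sample (shrubland biome) that released no
    CO2 at any temperature.  If ``sample_id`` is not given, a sample
    whose id carries ``biome_tag`` is chosen with the provided seed.
    Idempotent.  Returns the modified table and the chosen id.
    """
    rng = _as_rng(seed)
    ids = sorted(incubations["sample_id"].unique())
    if sample_id is None:
        candidates = [i for i in ids if biome_tag in i]
        if not candidates:
            candidates = ids
        sample_id = str(rng.choice(candidates))
    elif sample_id not in ids:
        raise ValueError(f"unknown sample id: {sample_id}")
    out = incubations.copy()
    mask = out["sample_id"] == sample_id
    out.loc[mask, "final_ppm"] = out.loc[mask, "initial_ppm"]
    return out, sample_id


def simulate_study(
    spec: DesignSpec = None,
    environment: EnvironmentModel = None,
    traits: TraitModel = None,
    protocol: IncubationProtocol = None,
    seed: int = 0,
    dead_sample: bool = True,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> tuple[pd.DataFrame, pd.DataFrame, str | None]:
    """Full synthetic study: (points, incubations, dead sample id).

    The seed feeds a hierarchical stream, one child per stage, so any
    stage can be reproduced in isolation from the same global seed.
    """
    spec = spec or DesignSpec()
    traits = traits or TraitModel()
    streams = np.random.SeedSequence(seed).spawn(4)
    design = generate_design(spec)
    points = generate_environment(design, environment, np.random.default_rng(streams[0]))
    points = assign_true_params(points, traits, np.random.default_rng(streams[1]), consts)
    incubations = simulate_incubations(
        points, spec, protocol, traits.rate_log_sd, np.random.default_rng(streams[2]), consts
    )
    dead_id = None
    if dead_sample:
        incubations, dead_id = inject_dead_sample(
            incubations, seed=np.random.default_rng(streams[3])
        )
    return points, incubations, dead_id
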