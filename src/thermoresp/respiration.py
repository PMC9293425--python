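"""Headspace-incubation flux calculation and curve assembly.

A respiration rate is measured by sealing a known dry mass of sieved
soil in a small vial, recording the headspace CO2 mixing ratio (ppm)
at the start and end of an incubation at a controlled temperature, and
converting the ppm increase to moles of CO2 with the ideal gas law.
The rate is

    rate [µmol g⁻¹ min⁻¹] = Δmol(CO2) · 1e6 / (dry mass · duration)

Per-sample (temperature, rate) series are assembled into
temperature-response curves; samples that never released CO2 (fewer
positive rates than the fitting minimum) are flagged as discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, ThermoConstants, celsius_to_kelvin

__all__ = [
    "IncubationRecord",
    "TemperatureResponseCurve",
    "mass_for_temperature",
    "default_headspace_volume",
    "headspace_moles",
    "respiration_rate",
    "build_curves",
    "records_to_frame",
    "frame_to_records",
    "rates_frame",
]

#: Default vial volume, mL (septum-sealed 12 mL exetainer).
DEFAULT_VIAL_VOLUME_ML = 12.0
#: Default particle density used to correct headspace volume for the
#: soil volume, g cm⁻³ (loose pumice soil).
DEFAULT_SOIL_DENSITY = 0.9
#: Minimum number of positive rates for a curve to enter fitting.
MIN_POSITIVE_POINTS = 5


@dataclass(frozen=True)
class IncubationRecord:
    """One sealed-vial incubation of one soil subsample."""

    sample_id: str
    target_T_C: float
    measured_T_C: float
    soil_dry_mass_g: float
    initial_ppm: float
    final_ppm: float
    duration_min: float
    vial_volume_ml: float = DEFAULT_VIAL_VOLUME_ML
    headspace_volume_ml: float | None = None

    def __post_init__(self) -> None:
        if not self.duration_min > 0:
            raise ValueError("duration_min must be positive")
        if not self.soil_dry_mass_g > 0:
            raise ValueError("soil_dry_mass_g must be positive")
        if self.initial_ppm < 0 or self.final_ppm < 0:
            raise ValueError("ppm readings must be non-negative")
        if self.headspace_volume_ml is not None:
            if not 0 < self.headspace_volume_ml <= self.vial_volume_ml:
                raise ValueError("need 0 < headspace_volume_ml <= vial_volume_ml")


@dataclass
class TemperatureResponseCurve:
    """One sample's (temperature, rate) series, sorted by temperature."""

    sample_id: str
    temperature_C: np.ndarray
    rate: np.ndarray  # µmol CO2 g⁻¹ min⁻¹; may contain non-positive values
    discarded: bool = False

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.rate > 0))

    def positive_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(temperature_C, rate) restricted to rate > 0, for log-space fitting."""
        mask = self.rate > 0
        return self.temperature_C[mask], self.rate[mask]


def mass_for_temperature(target_T_C: float) -> float:
    """Soil dry mass (g) used at a target incubation temperature (°C).

    Cooler incubations use more soil so that all incubations produce a
    comparable headspace CO2 increase in similar time.  Boundaries are
    half-open, closed on the left: [.., 20) → 4 g, [20, 30) → 3 g,
    [30, 38) → 2 g, [38, ..) → 1 g.
    """
    if not np.isfinite(target_T_C):
        raise ValueError("target temperature must be finite")
    if target_T_C < 20:
        return 4.0
    if target_T_C < 30:
        return 3.0
    if target_T_C < 38:
        return 2.0
    return 1.0


def default_headspace_volume(
    vial_volume_ml: float,
    soil_dry_mass_g: float,
    soil_density: float = DEFAULT_SOIL_DENSITY,
) -> float:
    """Vial gas volume (mL) after subtracting the soil volume.

    Uses a configurable soil density (g cm⁻³); an explicitly supplied
    headspace volume on the record always overrides this model.
    """
    hs = vial_volume_ml - soil_dry_mass_g / soil_density
    if not hs > 0:
        raise ValueError("soil volume exceeds vial volume")
    return hs


def headspace_moles(
    ppm: float,
    volume_ml: float,
    T_C: float,
    P_pa: float | None = None,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> float:
    """Moles of CO2 in a gas volume at mixing ratio ``ppm``, ideal gas.

    n = ppm·1e-6 · P·V/(R·T), with V in mL and T in °C.
    """
    if not volume_ml > 0:
        raise ValueError("volume must be positive")
    T_K = celsius_to_kelvin(T_C)
    if not T_K > 0:
        raise ValueError("temperature below absolute zero")
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    P = consts.P_atm if P_pa is None else P_pa
    return ppm * 1e-6 * P * (volume_ml * 1e-6) / (consts.R_gas * T_K)


def respiration_rate(
    record: IncubationRecord,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
    soil_density: float = DEFAULT_SOIL_DENSITY,
) -> float:
    """Respiration rate (µmol CO2 g⁻¹ min⁻¹) from one incubation.

    The headspace CO2 increase is converted to moles at the measured
    incubation temperature and divided by soil dry mass and duration.
    A CO2 decrease yields a negative rate, which is retained as data
    (downstream log-space fitting excludes it point-wise).
    """
    if record.headspace_volume_ml is not None:
        volume = record.headspace_volume_ml
    else:
        volume = default_headspace_volume(
            record.vial_volume_ml, record.soil_dry_mass_g, soil_density
        )
    delta_ppm = record.final_ppm - record.initial_ppm
    # signed moles: reuse the non-negative converter on |Δppm|
    mol = headspace_moles(abs(delta_ppm), volume, record.measured_T_C, None, consts)
    mol = mol if delta_ppm >= 0 else -mol
    return mol * 1e6 / (record.soil_dry_mass_g * record.duration_min)


def build_curves(
    records: Iterable[IncubationRecord],
    min_positive: int = MIN_POSITIVE_POINTS,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
    soil_density: float = DEFAULT_SOIL_DENSITY,
) -> tuple[list[TemperatureResponseCurve], dict[str, int]]:
    """Assemble per-sample temperature-response curves.

    Returns the curves (sorted by sample id, temperatures ascending)
    and a count summary ``{"kept": ..., "discarded": ...}``.  Curves
    with fewer than ``min_positive`` positive rates are flagged
    ``discarded`` and should not enter fitting.  Duplicate
    (sample, temperature) entries are averaged with a warning.
    """
    by_sample: dict[str, list[tuple[float, float]]] = {}
    for rec in records:
        rate = respiration_rate(rec, consts, soil_density)
        by_sample.setdefault(rec.sample_id, []).append((rec.measured_T_C, rate))

    curves: list[TemperatureResponseCurve] = []
    for sample_id in sorted(by_sample):
        pts = sorted(by_sample[sample_id])
        temps = np.array([t for t, _ in pts])
        rates = np.array([r for _, r in pts])
        uniq, inverse, counts = np.unique(temps, return_inverse=True, return_counts=True)
        if np.any(counts > 1):
            warnings.warn(
                f"sample {sample_id}: duplicate temperatures averaged", stacklevel=2
            )
            mean_rates = np.zeros_like(uniq)
            np.add.at(mean_rates, inverse, rates)
            mean_rates /= counts
            temps, rates = uniq, mean_rates
        curve = TemperatureResponseCurve(sample_id, temps, rates)
        curve.discarded = curve.n_positive < min_positive
        curves.append(curve)

    counts_summary = {
        "kept": sum(not c.discarded for c in curves),
        "discarded": sum(c.discarded for c in curves),
    }
    return curves, counts_summary


# ---------------------------------------------------------------------------
# delimited-text interchange

_RECORD_COLUMNS = [
    "sample_id",
    "target_T_C",
    "measured_T_C",
    "soil_dry_mass_g",
    "vial_volume_ml",
    "headspace_volume_ml",
    "initial_ppm",
    "final_ppm",
    "duration_min",
]


def records_to_frame(records: Sequence[IncubationRecord]) -> pd.DataFrame:
    """Incubation records as a tidy table (one row per vial)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "target_T_C": r.target_T_C,
            "measured_T_C": r.measured_T_C,
            "soil_dry_mass_g": r.soil_dry_mass_g,
            "vial_volume_ml": r.vial_volume_ml,
            "headspace_volume_ml": r.headspace_volume_ml,
            "initial_ppm": r.initial_ppm,
            "final_ppm": r.final_ppm,
            "duration_min": r.duration_min,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[IncubationRecord]:
    """Parse an incubations table; raises naming any missing column."""
    required = [c for c in _RECORD_COLUMNS if c not in ("headspace_volume_ml", "vial_volume_ml")]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"incubations table missing columns: {missing}")
    records = []
    for _, row in frame.iterrows():
        hs = row.get("headspace_volume_ml", None)
        hs = None if hs is None or pd.isna(hs) else float(hs)
        vial = row.get("vial_volume_ml", DEFAULT_VIAL_VOLUME_ML)
        vial = DEFAULT_VIAL_VOLUME_ML if pd.isna(vial) else float(vial)
        records.append(
            IncubationRecord(
                sample_id=str(row["sample_id"]),
                target_T_C=float(row["target_T_C"]),
                measured_T_C=float(row["measured_T_C"]),
                soil_dry_mass_g=float(row["soil_dry_mass_g"]),
                vial_volume_ml=vial,
                headspace_volume_ml=hs,
                initial_ppm=float(row["initial_ppm"]),
                final_ppm=float(row["final_ppm"]),
                duration_min=float(row["duration_min"]),
            )
        )
    return records


def rates_frame(curves: Sequence[TemperatureResponseCurve]) -> pd.DataFrame:
    """Rates table: one row per (sample, temperature) with a kept flag.

    ``kept`` marks points that enter log-space fitting: positive rate
    on a non-discarded curve.
    """
    rows = []
    for c in curves:
        for t, r in zip(c.temperature_C, c.rate):
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "temperature_C": t,
                    "rate_umol_g_min": r,
                    "kept": bool(r > 0 and not c.discarded),
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "temperature_C", "rate_umol_g_min", "kept"])


def curves_from_rates(
    frame: pd.DataFrame, min_positive: int = MIN_POSITIVE_POINTS
) -> list[TemperatureResponseCurve]:
    """Rebuild curves from a rates table (inverse of :func:`rates_frame`)."""
    missing = [c for c in ("sample_id", "temperature_C", "rate_umol_g_min") if c not in frame.columns]
    if missing:
        raise ValueError(f"rates table missing columns: {missing}")
    curves = []
    for sample_id, grp in frame.groupby("sample_id", sort=True):
        grp = grp.sort_values("temperature_C")
        curve = TemperatureResponseCurve(
            str(sample_id),
            grp["temperature_C"].to_numpy(dtype=float),
            grp["rate_umol_g_min"].to_numpy(dtype=float),
        )
        curve.discarded = curve.n_positive < min_positive
        curves.append(curve)
    return curves
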