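"""Closed-form temperature-response models and derived thermal traits.

Two models of the respiration rate R(T) of soil microbial communities:

* Macromolecular rate theory (MMRT) — transition-state theory with a
  non-zero activation heat capacity ΔCP‡, which curves the Arrhenius
  plot and produces a temperature optimum:

      ln R = ln(kB·T/h) − [ΔH‡_T0 + ΔCP‡(T−T0)]/(R·T)
                        + [ΔS‡_T0 + ΔCP‡·ln(T/T0)]/R

  The expression is exactly linear in (ΔH‡_T0, ΔCP‡, ΔS‡_T0) at fixed
  T, which is what makes the fit in :mod:`thermoresp.fitting` ordinary
  least squares.

* Lloyd & Taylor — the empirical exponential model
  ln R = ln R10 + E0·(1/span − 1/(T − T_off)) with a variable
  "activation energy" E0 and a zero-rate temperature offset.

From the MMRT parameters the module derives the thermal traits used as
community-level descriptors: the temperature optimum T_opt, the
inflection temperature T_inf (argmax of the absolute sensitivity
dR/dT), the reference rate R25, and the activation Gibbs energy ΔG‡_T0.
All temperatures here are Kelvin; the reporting layer converts to °C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, ThermoConstants

__all__ = [
    "MMRTParams",
    "LTParams",
    "ThermalTraits",
    "mmrt_log_rate",
    "t_opt",
    "t_inf",
    "r25",
    "delta_g0",
    "thermal_traits",
    "q10_mmrt",
    "q10_exact",
    "lt_log_rate",
    "q10_lt",
    "relative_sensitivity",
    "invert_traits",
]


@dataclass(frozen=True)
class MMRTParams:
    """MMRT activation parameters at the reference temperature T0.

    dH0 : ΔH‡_T0, activation enthalpy, J mol⁻¹
    dCp : ΔCP‡, activation heat capacity, J mol⁻¹ K⁻¹ (negative for
          enzyme-driven processes)
    dS0 : ΔS‡_T0, activation entropy, J mol⁻¹ K⁻¹
    """

    dH0: float
    dCp: float
    dS0: float

    def __post_init__(self) -> None:
        for name in ("dH0", "dCp", "dS0"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.dH0, self.dCp, self.dS0], dtype=float)


@dataclass(frozen=True)
class LTParams:
    """Lloyd & Taylor parameters.

    lnR10 : natural log of the basal rate at 10 °C
    E0    : temperature-sensitivity parameter, K
    """

    lnR10: float
    E0: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lnR10) and math.isfinite(self.E0)):
            raise ValueError("Lloyd & Taylor parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.lnR10, self.E0], dtype=float)


@dataclass(frozen=True)
class ThermalTraits:
    """Derived thermal traits of one MMRT parameter set.

    T_opt : temperature of maximal rate, K
    T_inf : inflection temperature (maximal dR/dT), K
    R25   : rate at the reference temperature, µmol CO2 g⁻¹ min⁻¹
    dG0   : activation Gibbs energy at T0, J mol⁻¹
    """

    T_opt: float
    T_inf: float
    R25: float
    dG0: float


def _check_T(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be strictly positive (Kelvin)")
    return T


def mmrt_log_rate(params: MMRTParams, T, consts: ThermoConstants = DEFAULT_CONSTANTS):
    """Natural log of the MMRT rate at temperature ``T`` (K).

    Vectorised over ``T``.  Raises ``ValueError`` for non-positive
    temperatures.
    """
    T = _check_T(T)
    c = consts
    pre = np.log(c.k_B * T / c.h_planck)
    enthalpic = (params.dH0 + params.dCp * (T - c.T0)) / (c.R_gas * T)
    entropic = (params.dS0 + params.dCp * np.log(T / c.T0)) / c.R_gas
    out = pre - enthalpic + entropic
    return out if out.ndim else float(out)


def t_opt(params: MMRTParams, consts: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Temperature optimum T_opt = (ΔH‡_T0 − ΔCP‡·T0)/(−ΔCP‡ − R), K.

    Defined only for ΔCP‡ < −R; otherwise the rate has no interior
    maximum and a ``ValueError`` is raised.
    """
    if not params.dCp < -consts.R_gas:
        raise ValueError("no temperature optimum: dCp must be < -R_gas")
    return (params.dH0 - params.dCp * consts.T0) / (-params.dCp - consts.R_gas)


def t_inf(params: MMRTParams, consts: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Inflection temperature, the argmax of the absolute sensitivity dR/dT.

    T_inf = (ΔH‡_T0 − ΔCP‡·T0)/(−ΔCP‡ + sqrt(−ΔCP‡·R)), K.
    Requires ΔCP‡ < 0; lies below T_opt whenever ΔCP‡ < −R.
    """
    if not params.dCp < 0:
        raise ValueError("no inflection point: dCp must be negative")
    denom = -params.dCp + math.sqrt(-params.dCp * consts.R_gas)
    return (params.dH0 - params.dCp * consts.T0) / denom


def delta_g0(params: MMRTParams, consts: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Activation Gibbs energy at T0: ΔG‡_T0 = ΔH‡_T0 − T0·ΔS‡_T0, J mol⁻¹."""
    return params.dH0 - consts.T0 * params.dS0


def r25(params: MMRTParams, consts: ThermoConstants = DEFAULT_CONSTANTS) -> float:
    """Rate at the reference temperature: exp(ln(kB·T0/h) − ΔG‡_T0/(R·T0)).

    Identically equal to ``exp(mmrt_log_rate(params, T0))`` — the ΔCP‡
    terms vanish at T0.
    """
    c = consts
    return math.exp(math.log(c.k_B * c.T0 / c.h_planck) - delta_g0(params, c) / (c.R_gas * c.T0))


def thermal_traits(params: MMRTParams, consts: ThermoConstants = DEFAULT_CONSTANTS) -> ThermalTraits:
    """All derived traits of one parameter set (raises if T_opt undefined)."""
    return ThermalTraits(
        T_opt=t_opt(params, consts),
        T_inf=t_inf(params, consts),
        R25=r25(params, consts),
        dG0=delta_g0(params, consts),
    )


def q10_mmrt(params: MMRTParams, T, consts: ThermoConstants = DEFAULT_CONSTANTS):
    """Relative temperature sensitivity Q10 from MMRT (printed-form approximation).

    Q10 = exp{10·[ΔH‡(T) − 5·ΔCP‡]/(R·T²)} with
    ΔH‡(T) = ΔH‡_T0 + ΔCP‡·(T − T0).  The factor 5 (half the 10 K
    interval) carries units of K.  ``q10_exact`` gives the
    interpretation-free forward rate ratio for comparison.
    """
    T = _check_T(T)
    dH_T = params.dH0 + params.dCp * (T - consts.T0)
    out = np.exp(10.0 * (dH_T - 5.0 * params.dCp) / (consts.R_gas * T**2))
    return out if out.ndim else float(out)


def q10_exact(
    params: MMRTParams,
    T,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
    interval: float = 10.0,
):
    """Exact forward rate ratio R(T + interval)/R(T) from MMRT."""
    T = np.asarray(T, dtype=float)
    out = np.exp(
        np.asarray(mmrt_log_rate(params, T + interval, consts))
        - np.asarray(mmrt_log_rate(params, T, consts))
    )
    return out if out.ndim else float(out)


def lt_log_rate(params: LTParams, T, consts: ThermoConstants = DEFAULT_CONSTANTS):
    """Natural log of the Lloyd & Taylor rate at temperature ``T`` (K).

    ln R = ln R10 + E0·(1/span − 1/(T − T_off)); equals ln R10 exactly
    at T = T_off + span = 283.15 K (10 °C).  Requires T > T_off.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= consts.lt_T0_offset):
        raise ValueError("temperature must exceed the Lloyd & Taylor zero-rate offset")
    out = params.lnR10 + params.E0 * (1.0 / consts.lt_ref_span - 1.0 / (T - consts.lt_T0_offset))
    return out if out.ndim else float(out)


def q10_lt(E0: float, T, consts: ThermoConstants = DEFAULT_CONSTANTS):
    """Q10 from the Lloyd & Taylor model: exp[10·E0/(T − T_off)²].

    Monotone decreasing in T, and > 1 whenever E0 > 0.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= consts.lt_T0_offset):
        raise ValueError("temperature must exceed the Lloyd & Taylor zero-rate offset")
    out = np.exp(10.0 * E0 / (T - consts.lt_T0_offset) ** 2)
    return out if out.ndim else float(out)


def relative_sensitivity(params: MMRTParams, T, consts: ThermoConstants = DEFAULT_CONSTANTS):
    """Relative sensitivity d ln R/dT = 1/T + [ΔH‡_T0 + ΔCP‡(T−T0)]/(R·T²), K⁻¹.

    Zero exactly at T_opt; independent of the substrate pool size,
    unlike the absolute sensitivity dR/dT.
    """
    T = _check_T(T)
    out = 1.0 / T + (params.dH0 + params.dCp * (T - consts.T0)) / (consts.R_gas * T**2)
    return out if out.ndim else float(out)


def invert_traits(
    T_opt_K: float,
    dCp: float,
    R25: float,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> MMRTParams:
    """Map a trait triple (T_opt, ΔCP‡, R25) back to MMRT parameters.

    Algebraic inversion of the T_opt and R25 closed forms, used by the
    synthetic-data generator to build parameter sets with prescribed
    traits:

        dH0 = T_opt·(−dCp − R) + dCp·T0
        dG0 = R·T0·[ln(kB·T0/h) − ln R25]
        dS0 = (dH0 − dG0)/T0

    Round-trips with :func:`t_opt` and :func:`r25` to numerical
    precision.
    """
    if not dCp < -consts.R_gas:
        raise ValueError("dCp must be < -R_gas for a defined optimum")
    if not T_opt_K > 0:
        raise ValueError("T_opt must be positive (Kelvin)")
    if not R25 > 0:
        raise ValueError("R25 must be positive")
    c = consts
    dH0 = T_opt_K * (-dCp - c.R_gas) + dCp * c.T0
    dG0 = c.R_gas * c.T0 * (math.log(c.k_B * c.T0 / c.h_planck) - math.log(R25))
    dS0 = (dH0 - dG0) / c.T0
    return MMRTParams(dH0=dH0, dCp=dCp, dS0=dS0)
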