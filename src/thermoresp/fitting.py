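"""Per-curve model fitting, uncertainty, and model comparison.

Both models are fitted on the log-rate scale, where each is exactly
linear in its parameters, so the fits are closed-form ordinary least
squares:

* MMRT: y = ln(rate) − ln(kB·T/h) regressed on the basis
  [−1/(R·T),  −(T−T0)/(R·T) + ln(T/T0)/R,  1/R]
  giving (ΔH‡_T0, ΔCP‡, ΔS‡_T0);
* Lloyd & Taylor: ln(rate) on [1, 1/span − 1/(T − T_off)] giving
  (ln R10, E0).

Fitting both on the same scale with the same residual convention makes
their AICc values directly comparable.  The AICc parameter count
includes the residual variance (k = 4 for MMRT, k = 3 for Lloyd &
Taylor).  Standard errors of the derived traits (T_opt, T_inf, R25)
are propagated from the parameter covariance by the delta method with
analytic gradients.

Non-positive rates are excluded point-wise (log undefined); a curve
needs at least ``min_positive`` positive rates to be fitted at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, ThermoConstants, celsius_to_kelvin, kelvin_to_celsius
from .respiration import MIN_POSITIVE_POINTS, TemperatureResponseCurve
from .thermo import (
    LTParams,
    MMRTParams,
    delta_g0,
    q10_mmrt,
    r25,
    t_inf,
    t_opt,
)

__all__ = [
    "FitResult",
    "ModelComparison",
    "TooFewPointsError",
    "aicc",
    "fit_mmrt",
    "fit_lloyd_taylor",
    "compare_models",
    "trait_se_delta",
    "trait_gradient",
    "q10_envelope",
    "fit_all",
    "fits_frame",
    "comparison_frame",
]


class TooFewPointsError(ValueError):
    """Curve has fewer positive rates than the fitting minimum."""


@dataclass
class FitResult:
    """One model fitted to one curve (log-rate scale)."""

    sample_id: str
    model: str  # "mmrt" | "lloyd_taylor"
    params: MMRTParams | LTParams
    covariance: np.ndarray  # over the parameters, in declaration order
    n_points: int
    rss: float
    sigma2: float
    aicc: float
    temperature_C: np.ndarray = field(repr=False, default=None)
    traits: dict | None = None  # reporting units (°C, rate); MMRT only
    traits_se: dict | None = None
    extrapolated_optimum: bool = False  # T_opt beyond max measured T


@dataclass(frozen=True)
class ModelComparison:
    """AICc comparison of the two models on one curve."""

    sample_id: str
    aicc_mmrt: float
    aicc_lt: float

    @property
    def delta(self) -> float:
        """aicc_lt − aicc_mmrt; positive favours MMRT."""
        return self.aicc_lt - self.aicc_mmrt

    @property
    def winner(self) -> str:
        return "mmrt" if self.delta > 0 else "lloyd_taylor"


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion for a Gaussian fit.

    n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1), where ``k`` counts all
    estimated quantities including the residual variance.  Requires
    n > k + 1 (otherwise the small-sample correction is undefined).
    """
    if not n > k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares with covariance sigma2·(XᵀX)⁻¹; raises if singular."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular design matrix (degenerate temperature set)")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, cov, rss


def _positive_points(
    curve: TemperatureResponseCurve, min_positive: int
) -> tuple[np.ndarray, np.ndarray]:
    temps, rates = curve.positive_points()
    if len(rates) < min_positive:
        raise TooFewPointsError(
            f"sample {curve.sample_id}: {len(rates)} positive rates < {min_positive}"
        )
    return temps, rates


def fit_mmrt(
    curve: TemperatureResponseCurve,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
    min_positive: int = MIN_POSITIVE_POINTS,
) -> FitResult:
    """Fit MMRT to one curve by exact linear least squares.

    Derived traits and their delta-method standard errors are attached
    when the fitted ΔCP‡ < −R (otherwise the optimum is undefined and
    ``traits`` is None).
    """
    temps_c, rates = _positive_points(curve, min_positive)
    T = celsius_to_kelvin(temps_c)
    c = consts
    y = np.log(rates) - np.log(c.k_B * T / c.h_planck)
    X = np.column_stack(
        [
            -1.0 / (c.R_gas * T),
            -(T - c.T0) / (c.R_gas * T) + np.log(T / c.T0) / c.R_gas,
            np.full_like(T, 1.0 / c.R_gas),
        ]
    )
    beta, cov, rss = _ols(X, y)
    params = MMRTParams(dH0=beta[0], dCp=beta[1], dS0=beta[2])
    n = len(y)
    result = FitResult(
        sample_id=curve.sample_id,
        model="mmrt",
        params=params,
        covariance=cov,
        n_points=n,
        rss=rss,
        sigma2=rss / (n - 3),
        aicc=aicc(rss, n, k=4),
        temperature_C=temps_c,
    )
    if params.dCp < -c.R_gas:
        topt_k = t_opt(params, c)
        tinf_k = t_inf(params, c)
        result.traits = {
            "T_opt_C": kelvin_to_celsius(topt_k),
            "T_inf_C": kelvin_to_celsius(tinf_k),
            "R25": r25(params, c),
            "dG0_J_mol": delta_g0(params, c),
        }
        result.traits_se = {
            t: trait_se_delta(params, cov, t, c) for t in ("T_opt_C", "T_inf_C", "R25")
        }
        result.extrapolated_optimum = bool(kelvin_to_celsius(topt_k) > temps_c.max())
    return result


def fit_lloyd_taylor(
    curve: TemperatureResponseCurve,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
    min_positive: int = MIN_POSITIVE_POINTS,
) -> FitResult:
    """Fit the Lloyd & Taylor model to one curve (log scale OLS)."""
    temps_c, rates = _positive_points(curve, min_positive)
    T = celsius_to_kelvin(temps_c)
    c = consts
    if np.any(T <= c.lt_T0_offset):
        raise ValueError("temperatures at or below the Lloyd & Taylor zero-rate offset")
    y = np.log(rates)
    X = np.column_stack(
        [
            np.ones_like(T),
            1.0 / c.lt_ref_span - 1.0 / (T - c.lt_T0_offset),
        ]
    )
    beta, cov, rss = _ols(X, y)
    n = len(y)
    return FitResult(
        sample_id=curve.sample_id,
        model="lloyd_taylor",
        params=LTParams(lnR10=beta[0], E0=beta[1]),
        covariance=cov,
        n_points=n,
        rss=rss,
        sigma2=rss / (n - 2),
        aicc=aicc(rss, n, k=3),
        temperature_C=temps_c,
    )


def trait_gradient(
    params: MMRTParams, trait: str, consts: ThermoConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """Analytic gradient of a derived trait w.r.t. (dH0, dCp, dS0).

    T_opt depends on (dH0, dCp) only; R25 on (dH0, dS0) only — so each
    trait's SE is invariant to uncertainty in the parameter it
    excludes.
    """
    R = consts.R_gas
    T0 = consts.T0
    N = params.dH0 - params.dCp * T0
    if trait == "T_opt_C":
        D = -params.dCp - R
        if not D > 0:
            raise ValueError("T_opt undefined (dCp >= -R_gas)")
        return np.array([1.0 / D, (-T0 * D + N) / D**2, 0.0])
    if trait == "T_inf_C":
        if not params.dCp < 0:
            raise ValueError("T_inf undefined (dCp >= 0)")
        s = math.sqrt(-params.dCp * R)
        D = -params.dCp + s
        dD_ddCp = -1.0 - R / (2.0 * s)
        return np.array([1.0 / D, (-T0 * D - N * dD_ddCp) / D**2, 0.0])
    if trait == "R25":
        val = r25(params, consts)
        return np.array([-val / (R * T0), 0.0, val / R])
    raise ValueError(f"unknown trait: {trait}")


def trait_se_delta(
    params: MMRTParams,
    covariance: np.ndarray,
    trait: str,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> float:
    """Delta-method standard error of a derived trait."""
    g = trait_gradient(params, trait, consts)
    var = float(g @ covariance @ g)
    return math.sqrt(max(var, 0.0))


def compare_models(mmrt_fit: FitResult, lt_fit: FitResult) -> ModelComparison:
    """AICc comparison; refuses fits made on different point sets."""
    if mmrt_fit.sample_id != lt_fit.sample_id:
        raise ValueError("fits belong to different samples")
    if mmrt_fit.n_points != lt_fit.n_points or not np.array_equal(
        mmrt_fit.temperature_C, lt_fit.temperature_C
    ):
        raise ValueError("fits use different point sets; comparison invalid")
    return ModelComparison(
        sample_id=mmrt_fit.sample_id, aicc_mmrt=mmrt_fit.aicc, aicc_lt=lt_fit.aicc
    )


def q10_envelope(
    fits: dict[str, list[FitResult]],
    T_grid_C: np.ndarray,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Treatment-level Q10 mean ± SE curves from replicate MMRT fits.

    ``fits`` maps a group label to that group's replicate fits (e.g.
    biome × distance with depths pooled, n = 6).  At each grid
    temperature, Q10 is evaluated from each replicate's parameters and
    summarised as mean ± SE across replicates.
    """
    T_grid_C = np.asarray(T_grid_C, dtype=float)
    rows = []
    for group, group_fits in fits.items():
        if len(group_fits) < 2:
            raise ValueError(f"group {group!r}: need at least 2 replicate fits")
        curves = np.vstack(
            [
                q10_mmrt(f.params, celsius_to_kelvin(T_grid_C), consts)
                for f in group_fits
            ]
        )
        n = curves.shape[0]
        mean = curves.mean(axis=0)
        se = curves.std(axis=0, ddof=1) / math.sqrt(n)
        for t, m, s in zip(T_grid_C, mean, se):
            rows.append(
                {"group": group, "temperature_C": t, "q10_mean": m, "q10_se": s, "n": n}
            )
    return pd.DataFrame(rows)


def fit_all(
    curves,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
    min_positive: int = MIN_POSITIVE_POINTS,
) -> tuple[list[FitResult], list[FitResult], list[ModelComparison]]:
    """Fit both models to every non-discarded curve.

    Returns (mmrt fits, Lloyd & Taylor fits, comparisons), skipping
    discarded curves.
    """
    mmrt_fits, lt_fits, comparisons = [], [], []
    for curve in curves:
        if curve.discarded:
            continue
        m = fit_mmrt(curve, consts, min_positive)
        l = fit_lloyd_taylor(curve, consts, min_positive)
        mmrt_fits.append(m)
        lt_fits.append(l)
        comparisons.append(compare_models(m, l))
    return mmrt_fits, lt_fits, comparisons


def fits_frame(mmrt_fits, lt_fits) -> pd.DataFrame:
    """Fits table, one row per sample × model, parameters in kJ and °C."""
    rows = []
    for f in mmrt_fits:
        p: MMRTParams = f.params
        se = np.sqrt(np.diag(f.covariance))
        row = {
            "sample_id": f.sample_id,
            "model": "mmrt",
            "dH0_kJ_mol": p.dH0 / 1e3,
            "dH0_kJ_mol_se": se[0] / 1e3,
            "dCp_kJ_mol_K": p.dCp / 1e3,
            "dCp_kJ_mol_K_se": se[1] / 1e3,
            "dS0_J_mol_K": p.dS0,
            "dS0_J_mol_K_se": se[2],
            "lnR10": np.nan,
            "lnR10_se": np.nan,
            "E0_K": np.nan,
            "E0_K_se": np.nan,
            "n_points": f.n_points,
            "rss_log": f.rss,
            "aicc": f.aicc,
            "extrapolated_optimum": f.extrapolated_optimum,
        }
        traits = f.traits or {}
        traits_se = f.traits_se or {}
        row["T_opt_C"] = traits.get("T_opt_C", np.nan)
        row["T_opt_C_se"] = traits_se.get("T_opt_C", np.nan)
        row["T_inf_C"] = traits.get("T_inf_C", np.nan)
        row["T_inf_C_se"] = traits_se.get("T_inf_C", np.nan)
        row["R25_umol_g_min"] = traits.get("R25", np.nan)
        row["R25_umol_g_min_se"] = traits_se.get("R25", np.nan)
        rows.append(row)
    for f in lt_fits:
        p: LTParams = f.params
        se = np.sqrt(np.diag(f.covariance))
        rows.append(
            {
                "sample_id": f.sample_id,
                "model": "lloyd_taylor",
                "dH0_kJ_mol": np.nan,
                "dH0_kJ_mol_se": np.nan,
                "dCp_kJ_mol_K": np.nan,
                "dCp_kJ_mol_K_se": np.nan,
                "dS0_J_mol_K": np.nan,
                "dS0_J_mol_K_se": np.nan,
                "lnR10": p.lnR10,
                "lnR10_se": se[0],
                "E0_K": p.E0,
                "E0_K_se": se[1],
                "n_points": f.n_points,
                "rss_log": f.rss,
                "aicc": f.aicc,
                "extrapolated_optimum": False,
                "T_opt_C": np.nan,
                "T_opt_C_se": np.nan,
                "T_inf_C": np.nan,
                "T_inf_C_se": np.nan,
                "R25_umol_g_min": np.nan,
                "R25_umol_g_min_se": np.nan,
            }
        )
    return pd.DataFrame(rows)


def comparison_frame(comparisons) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "aicc_mmrt": c.aicc_mmrt,
                "aicc_lt": c.aicc_lt,
                "delta_aicc": c.delta,
                "winner": c.winner,
            }
            for c in comparisons
        ]
    )
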