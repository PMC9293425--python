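"""Published treatment-level summary tables from the geothermal field campaign.

Cell means ± standard errors (n = 3 transects per cell) of the
environment covariates and of the fitted MMRT traits, for the full
3 distances × 2 biomes × 2 depths design.  These values anchor the
defaults of the synthetic-data generator and serve as fixtures for the
summary-aggregation machinery (marginal means over a balanced design
are unweighted means of cell means).

Units follow the published convention: MET in °C, Ws in m³ m⁻³, C and
N in % mass, ΔH‡_T0 in kJ mol⁻¹, ΔCP‡ in kJ mol⁻¹ K⁻¹, temperatures in
°C, R25 in µmol CO2 g⁻¹ min⁻¹.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["environment_summary", "mmrt_trait_summary"]

_FACTORS = ["biome", "depth", "distance_m"]

# (biome, depth, distance, MET, se, Ws, se, pH, se, C, se, N, se, CN, se)
_ENV_CELLS = [
    ("grassland", "0-50 mm", 2, 24.2, 1.7, 0.35, 0.09, 4.1, 0.1, 15.1, 4.8, 0.89, 0.16, 16.0, 2.5),
    ("grassland", "0-50 mm", 10, 20.9, 1.5, 0.31, 0.09, 4.5, 0.1, 8.3, 1.6, 0.64, 0.12, 13.0, 0.0),
    ("grassland", "0-50 mm", 30, 16.9, 0.8, 0.42, 0.08, 4.8, 0.1, 9.8, 2.5, 0.78, 0.21, 12.3, 0.3),
    ("grassland", "50-100 mm", 2, 31.6, 2.8, 0.35, 0.07, 4.5, 0.1, 5.0, 1.3, 0.37, 0.09, 13.0, 0.6),
    ("grassland", "50-100 mm", 10, 24.7, 2.4, 0.30, 0.11, 4.7, 0.1, 3.8, 1.8, 0.29, 0.12, 12.7, 0.7),
    ("grassland", "50-100 mm", 30, 19.6, 0.8, 0.20, 0.02, 4.9, 0.1, 4.1, 1.3, 0.29, 0.10, 15.0, 1.0),
    ("kanuka", "0-50 mm", 2, 35.8, 0.3, 0.28, 0.05, 3.1, 0.1, 6.3, 1.3, 0.26, 0.04, 23.7, 1.8),
    ("kanuka", "0-50 mm", 10, 30.8, 0.7, 0.38, 0.07, 3.1, 0.2, 27.9, 8.7, 0.98, 0.10, 27.0, 5.5),
    ("kanuka", "0-50 mm", 30, 21.8, 0.2, 0.40, 0.03, 3.5, 0.4, 32.3, 5.6, 1.45, 0.12, 22.7, 5.2),
    ("kanuka", "50-100 mm", 2, 48.3, 5.1, 0.29, 0.01, 3.4, 0.1, 1.2, 0.1, 0.07, 0.01, 18.5, 1.5),
    ("kanuka", "50-100 mm", 10, 38.8, 1.3, 0.34, 0.05, 3.1, 0.2, 8.4, 4.0, 0.33, 0.10, 23.0, 3.5),
    ("kanuka", "50-100 mm", 30, 27.8, 0.5, 0.21, 0.01, 4.2, 0.4, 6.6, 2.3, 0.42, 0.13, 14.7, 2.2),
]

_ENV_COLUMNS = _FACTORS + [
    "MET_C", "MET_C_se",
    "Ws_m3m3", "Ws_m3m3_se",
    "pH", "pH_se",
    "C_pct", "C_pct_se",
    "N_pct", "N_pct_se",
    "CN", "CN_se",
]

# (biome, depth, distance, dH0 kJ/mol, se, dCp kJ/mol/K, se, Tinf °C, se, Topt °C, se, R25, se)
_MMRT_CELLS = [
    ("grassland", "0-50 mm", 2, 73.4, 3.2, -1.4, 0.2, 54.2, 3.9, 82.4, 6.6, 23.9, 6.4),
    ("grassland", "0-50 mm", 10, 65.8, 6.6, -2.6, 0.4, 34.9, 4.6, 54.0, 6.6, 23.8, 7.2),
    ("grassland", "0-50 mm", 30, 68.5, 2.3, -1.3, 0.1, 53.6, 6.3, 82.5, 8.7, 40.8, 8.9),
    ("grassland", "50-100 mm", 2, 71.0, 4.1, -2.9, 0.3, 33.7, 2.8, 51.3, 3.8, 12.8, 1.4),
    ("grassland", "50-100 mm", 10, 60.0, 3.9, -3.2, 0.9, 31.6, 5.4, 49.8, 9.6, 9.4, 3.1),
    ("grassland", "50-100 mm", 30, 49.7, 9.8, -3.4, 1.7, 32.2, 6.5, 51.5, 10.9, 8.3, 0.7),
    ("kanuka", "0-50 mm", 2, 65.8, 2.1, -1.9, 0.4, 41.9, 6.4, 65.4, 9.7, 16.8, 4.7),
    ("kanuka", "0-50 mm", 10, 75.1, 1.7, -1.3, 0.2, 57.8, 6.3, 60.1, 8.8, 35.1, 6.4),
    ("kanuka", "0-50 mm", 30, 77.7, 1.7, -1.1, 0.2, 69.3, 8.1, 103.1, 12.1, 53.5, 9.1),
    ("kanuka", "50-100 mm", 2, 38.6, 4.5, -1.3, 0.4, 34.2, 10.0, 62.6, 16.3, 4.3, 0.8),
    ("kanuka", "50-100 mm", 10, 61.9, 2.4, -1.9, 0.2, 37.7, 1.1, 60.1, 2.1, 11.9, 2.1),
    ("kanuka", "50-100 mm", 30, 59.2, 0.7, -2.1, 0.2, 34.4, 1.8, 55.4, 3.3, 15.8, 2.1),
]

_MMRT_COLUMNS = _FACTORS + [
    "dH0_kJ_mol", "dH0_kJ_mol_se",
    "dCp_kJ_mol_K", "dCp_kJ_mol_K_se",
    "T_inf_C", "T_inf_C_se",
    "T_opt_C", "T_opt_C_se",
    "R25_umol_g_min", "R25_umol_g_min_se",
]


def environment_summary() -> pd.DataFrame:
    """Cell means ± SE of the environment covariates per treatment cell."""
    return pd.DataFrame(_ENV_CELLS, columns=_ENV_COLUMNS)


def mmrt_trait_summary() -> pd.DataFrame:
    """Cell means ± SE of the fitted MMRT parameters and traits per cell."""
    return pd.DataFrame(_MMRT_CELLS, columns=_MMRT_COLUMNS)
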