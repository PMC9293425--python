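"""End-to-end drivers: simulate → rates → fit → stats → report.

Each stage is a pure function of its input tables, so piping the CSV
outputs of one stage into the next is equivalent to running the
all-in-one driver.  Output tables carry units in their column names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fitting, respiration, simulate, stats
from .config import StudyConfig, config_hash

__all__ = [
    "StudyResult",
    "run_simulate",
    "run_rates",
    "run_fit",
    "run_stats",
    "run_study",
    "format_report",
]

log = logging.getLogger("thermoresp")


def write_table(frame: pd.DataFrame, path_or_buf) -> None:
    """Write a CSV that round-trips float64 exactly (%.17g formatting)."""
    frame.to_csv(path_or_buf, index=False, float_format="%.17g")


def read_table(path_or_buf) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` without float drift."""
    return pd.read_csv(path_or_buf, float_precision="round_trip")

#: traits analysed against the treatments and the environment
TRAIT_COLUMNS = ["dH0_kJ_mol", "dCp_kJ_mol_K", "T_opt_C", "T_inf_C", "R25_umol_g_min"]


@dataclass
class StudyResult:
    points: pd.DataFrame
    incubations: pd.DataFrame
    rates: pd.DataFrame
    fits: pd.DataFrame
    comparison: pd.DataFrame
    summary: pd.DataFrame
    anova: pd.DataFrame
    stepwise: pd.DataFrame
    stepwise_results: dict
    lmm: pd.DataFrame
    q10: pd.DataFrame
    dead_sample: str | None


def run_simulate(cfg: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame, str | None]:
    """Generate the synthetic study defined by the configuration."""
    points, incubations, dead_id = simulate.simulate_study(
        spec=cfg.design,
        environment=cfg.environment,
        traits=cfg.traits,
        protocol=cfg.protocol,
        seed=cfg.seed,
        dead_sample=cfg.dead_sample,
        consts=cfg.constants,
    )
    log.info(
        "simulated study: seed=%d config=%s points=%d incubations=%d dead=%s",
        cfg.seed, config_hash(cfg), len(points), len(incubations), dead_id,
    )
    return points, incubations, dead_id


def run_rates(incubations: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    """Incubation readings → rates table with kept flags."""
    records = respiration.frame_to_records(incubations)
    curves, counts = respiration.build_curves(
        records,
        min_positive=cfg.fitting.min_positive_points,
        consts=cfg.constants,
        soil_density=cfg.protocol.soil_density,
    )
    log.info("curves: kept=%d discarded=%d", counts["kept"], counts["discarded"])
    return respiration.rates_frame(curves)


def run_fit(rates: pd.DataFrame, cfg: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Rates table → fits and model-comparison tables."""
    curves = respiration.curves_from_rates(rates, cfg.fitting.min_positive_points)
    fittable = [c for c in curves if not c.discarded]
    if not fittable:
        raise ValueError("no fittable curves in the rates table")
    mmrt_fits, lt_fits, comparisons = fitting.fit_all(
        curves, cfg.constants, cfg.fitting.min_positive_points
    )
    n_neg = int((rates["rate_umol_g_min"] <= 0).sum())
    log.info("fitted %d curves (%d non-positive rates excluded point-wise)",
             len(mmrt_fits), n_neg)
    return fitting.fits_frame(mmrt_fits, lt_fits), fitting.comparison_frame(comparisons), mmrt_fits


def _q10_grid(cfg: StudyConfig) -> np.ndarray:
    start, stop, step = cfg.fitting.q10_grid_C
    return np.arange(start, stop + step / 2, step)


def run_stats(
    points: pd.DataFrame,
    fits: pd.DataFrame,
    cfg: StudyConfig,
    mmrt_fits: list | None = None,
) -> dict:
    """Treatment summaries, ANOVA, stepwise regression and LMM tables."""
    mmrt_rows = fits[fits["model"] == "mmrt"].rename(columns={"sample_id": "point_id"})
    merged = points.merge(mmrt_rows, on="point_id", how="inner")

    summaries = []
    for var in TRAIT_COLUMNS:
        s = stats.summarize_treatments(merged, var, cfg.stats.anova_factors)
        s.insert(0, "variable", var)
        summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True)

    anova_rows = []
    for var in TRAIT_COLUMNS:
        res = stats.three_way_anova(merged, var, cfg.stats.anova_factors)
        tab = res.table.reset_index(names="term")
        tab.insert(0, "response", var)
        tab["r_squared"] = res.r_squared
        anova_rows.append(tab)
    anova = pd.concat(anova_rows, ignore_index=True)

    step_rows = []
    step_results = {}
    for var in TRAIT_COLUMNS:
        res = stats.backwards_stepwise(
            merged, var, cfg.stats.stepwise_covariates, cfg.stats.alpha
        )
        step_results[var] = res
        for term in res.retained:
            step_rows.append(
                {
                    "response": var,
                    "term": term,
                    "estimate": res.params.get(term, np.nan),
                    "se": res.bse.get(term, np.nan),
                    "p": res.term_pvalues.get(term, np.nan),
                }
            )
        if not res.retained:
            step_rows.append(
                {"response": var, "term": "(intercept only)", "estimate": res.params.iloc[0],
                 "se": res.bse.iloc[0], "p": np.nan}
            )
    stepwise = pd.DataFrame(step_rows, columns=["response", "term", "estimate", "se", "p"])

    fixed_rhs = "*".join(cfg.stats.stepwise_covariates)
    lmm_rows = []
    for var in TRAIT_COLUMNS:
        cmp_ = stats.compare_random_intercept(merged, var, fixed_rhs, cfg.stats.lmm_group)
        lmm_rows.append(
            {
                "response": var,
                "aicc_fixed": cmp_.aicc_fixed,
                "aicc_random_intercept": cmp_.aicc_mixed,
                "random_effect_improves": cmp_.improved,
            }
        )
    lmm = pd.DataFrame(lmm_rows)

    q10 = pd.DataFrame()
    if mmrt_fits:
        fit_by_id = {f.sample_id: f for f in mmrt_fits}
        groups: dict[str, list] = {}
        for _, row in points.iterrows():
            f = fit_by_id.get(row["point_id"])
            if f is None:
                continue
            groups.setdefault(f"{row['biome']}/{row['distance_m']}m", []).append(f)
        groups = {g: fl for g, fl in groups.items() if len(fl) >= 2}
        if groups:
            q10 = fitting.q10_envelope(groups, _q10_grid(cfg), cfg.constants)

    return {"summary": summary, "anova": anova, "stepwise": stepwise,
            "stepwise_results": step_results, "lmm": lmm, "q10": q10}


def run_study(cfg: StudyConfig) -> StudyResult:
    """All stages on one configuration."""
    points, incubations, dead_id = run_simulate(cfg)
    rates = run_rates(incubations, cfg)
    fits, comparison, mmrt_fits = run_fit(rates, cfg)
    tables = run_stats(points, fits, cfg, mmrt_fits)
    return StudyResult(
        points=points,
        incubations=incubations,
        rates=rates,
        fits=fits,
        comparison=comparison,
        summary=tables["summary"],
        anova=tables["anova"],
        stepwise=tables["stepwise"],
        stepwise_results=tables["stepwise_results"],
        lmm=tables["lmm"],
        q10=tables["q10"],
        dead_sample=dead_id,
    )


def format_report(result: StudyResult) -> str:
    """Human-readable run summary (treatment tables and Q10 envelope)."""
    lines = []
    n_points = len(result.points)
    n_fits = result.fits[result.fits["model"] == "mmrt"]["sample_id"].nunique()
    lines.append("Synthetic geothermal-gradient study")
    lines.append(f"  sampling points: {n_points}")
    lines.append(f"  incubations: {len(result.incubations)} "
                 f"({2 * len(result.incubations)} CO2 readings)")
    lines.append(f"  fitted curves: {n_fits}"
                 + (f" (dead sample: {result.dead_sample})" if result.dead_sample else ""))
    wins = (result.comparison["winner"] == "mmrt").sum()
    lines.append(f"  MMRT preferred by AICc on {wins}/{len(result.comparison)} curves")
    lines.append("")
    lines.append("Treatment means (mean ± SE per biome × depth × distance):")
    for var, grp in result.summary.groupby("variable"):
        lines.append(f"  {var}:")
        for _, r in grp.iterrows():
            lines.append(
                f"    {r['biome']:<10} {r['depth']:<10} {r['distance_m']:>3} m: "
                f"{r['mean']:8.1f} ± {0 if np.isnan(r['se']) else r['se']:.1f} (n={int(r['n'])})"
            )
    lines.append("")
    lines.append("Backwards stepwise regression (retained terms):")
    for _, r in result.stepwise.iterrows():
        p_txt = "" if np.isnan(r["p"]) else f", p={r['p']:.3g}"
        lines.append(f"  {r['response']:<16} {r['term']:<16} {r['estimate']:.3g}{p_txt}")
    lines.append("")
    lines.append("Random intercept (transect) by AICc:")
    for _, r in result.lmm.iterrows():
        verdict = "improves" if r["random_effect_improves"] else "does not improve"
        lines.append(f"  {r['response']:<16} {verdict} "
                     f"(fixed {r['aicc_fixed']:.1f} vs mixed {r['aicc_random_intercept']:.1f})")
    if len(result.q10):
        lines.append("")
        lines.append("Q10 envelope (mean ± SE at 10/25/40 °C):")
        for group, grp in result.q10.groupby("group"):
            sel = grp[grp["temperature_C"].isin([10.0, 25.0, 40.0])]
            txt = "  ".join(
                f"{r['temperature_C']:.0f}°C: {r['q10_mean']:.2f}±{r['q10_se']:.2f}"
                for _, r in sel.iterrows()
            )
            lines.append(f"  {group:<16} {txt}")
    return "\n".join(lines)
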