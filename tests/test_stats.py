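"""Treatment summaries, factorial ANOVA, stepwise regression, mixed model."""

import itertools

import numpy as np
import pandas as pd
import pytest

from thermoresp.stats import (
    backwards_stepwise,
    compare_random_intercept,
    lmm_random_intercept,
    summarize_treatments,
    three_way_anova,
    unweighted_marginal_means,
    variance_explained,
)


def factorial_frame(rng, reps=2, noise=1.0):
    rows = []
    for b, d, i, r in itertools.product(("x", "y"), ("lo", "hi"), (1, 2), range(reps)):
        rows.append({"biome": b, "depth": d, "distance_m": i,
                     "y": rng.normal(0, noise), "rep": r})
    return pd.DataFrame(rows)


class TestSummaries:
    def test_cell_means_and_se(self):
        df = pd.DataFrame(
            {"biome": ["x"] * 3 + ["y"] * 3, "depth": ["d"] * 6, "distance_m": [2] * 6,
             "v": [1.0, 2.0, 3.0, 5.0, 5.0, 5.0]}
        )
        out = summarize_treatments(df, "v")
        x = out[out.biome == "x"].iloc[0]
        assert x["mean"] == 2.0 and x["n"] == 3
        assert x["se"] == pytest.approx(1.0 / np.sqrt(3))
        assert out[out.biome == "y"].iloc[0]["se"] == 0.0

    def test_marginal_mean_is_unweighted_mean_of_cell_means(self):
        cells = pd.DataFrame(
            {"biome": ["x", "x", "y", "y"], "depth": ["a", "b", "a", "b"],
             "v": [1.0, 3.0, 10.0, 20.0]}
        )
        out = unweighted_marginal_means(cells, "v", "biome")
        assert out[out.biome == "x"]["mean"].iloc[0] == 2.0
        assert out[out.biome == "y"]["mean"].iloc[0] == 15.0

    def test_missing_variable_rejected(self):
        with pytest.raises(ValueError, match="nope"):
            summarize_treatments(pd.DataFrame({"biome": ["x"]}), "nope")


def hand_anova_ss(df, response):
    """Independent balanced-design SS computation from cell/marginal means."""
    grand = df[response].mean()
    n = len(df)
    ss = {}
    factors = ["biome", "depth", "distance_m"]
    means = {f: df.groupby(f)[response].mean() for f in factors}
    for f in factors:
        counts = df.groupby(f)[response].count()
        ss[f] = float((counts * (means[f] - grand) ** 2).sum())
    for f1, f2 in itertools.combinations(factors, 2):
        cell = df.groupby([f1, f2])[response].agg(["mean", "count"])
        tot = 0.0
        for (a, b), row in cell.iterrows():
            expected = means[f1][a] + means[f2][b] - grand
            tot += row["count"] * (row["mean"] - expected) ** 2
        ss[f"{f1} x {f2}"] = tot
    cell = df.groupby(factors)[response].agg(["mean", "count"])
    two_way = {k: v for k, v in ss.items() if " x " in k}
    tot = 0.0
    for (a, b, c), row in cell.iterrows():
        # three-way deviation from the additive + two-way reconstruction
        pairs = (
            df[(df.biome == a) & (df.depth == b)][response].mean()
            + df[(df.biome == a) & (df.distance_m == c)][response].mean()
            + df[(df.depth == b) & (df.distance_m == c)][response].mean()
        )
        mains = means["biome"][a] + means["depth"][b] + means["distance_m"][c]
        expected = pairs - mains + grand
        tot += row["count"] * (row["mean"] - expected) ** 2
    ss["biome x depth x distance_m"] = tot
    ss["total"] = float(((df[response] - grand) ** 2).sum())
    return ss


class TestThreeWayAnova:
    def test_pure_factor_contrast_is_fully_attributed(self, rng):
        df = factorial_frame(rng, reps=3, noise=0.0)
        df["y"] = np.where(df.biome == "x", 1.0, -1.0)
        res = three_way_anova(df, "y")
        assert res.table.loc["biome", "sum_sq"] == pytest.approx(len(df), rel=1e-9)
        others = res.table.drop(index=["biome", "Residual"])["sum_sq"]
        assert np.allclose(others, 0.0, atol=1e-18)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_response_has_no_variance_to_explain(self, rng):
        df = factorial_frame(rng, reps=2)
        df["y"] = 7.0
        res = three_way_anova(df, "y")
        assert np.allclose(res.table["sum_sq"], 0.0, atol=1e-18)

    def test_balanced_ss_match_hand_computation(self, rng):
        df = factorial_frame(rng, reps=3)
        res = three_way_anova(df, "y")
        expected = hand_anova_ss(df, "y")
        for term in ("biome", "depth", "distance_m", "biome x depth",
                     "biome x distance_m", "depth x distance_m",
                     "biome x depth x distance_m"):
            assert res.table.loc[term, "sum_sq"] == pytest.approx(expected[term], rel=1e-9)

    def test_decomposition_and_order_invariance(self, rng):
        df = factorial_frame(rng, reps=2)
        res1 = three_way_anova(df, "y", ("biome", "depth", "distance_m"))
        total = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert res1.table["sum_sq"].sum() == pytest.approx(total, rel=1e-9)
        res2 = three_way_anova(df, "y", ("distance_m", "biome", "depth"))
        for term in ("biome", "depth", "distance_m"):
            assert res2.table.loc[term, "sum_sq"] == pytest.approx(
                res1.table.loc[term, "sum_sq"], rel=1e-9
            )


def covariate_frame(rng, n=40):
    return pd.DataFrame(
        {
            "MET_C": rng.uniform(15, 50, n),
            "Ws_m3m3": rng.uniform(0.2, 0.42, n),
            "C_pct": rng.uniform(1, 30, n),
        }
    )


class TestBackwardsStepwise:
    def test_recovers_single_true_covariate(self, rng):
        df = covariate_frame(rng)
        df["y"] = 2.0 * df["C_pct"] + rng.normal(0, 0.5, len(df))
        res = backwards_stepwise(df, "y")
        assert res.retained == ["C_pct"]
        assert res.params["C_pct"] == pytest.approx(2.0, abs=3 * res.bse["C_pct"])

    def test_pure_noise_usually_reduces_to_intercept(self):
        # every one of the 7 candidate terms must survive its own exit
        # F-test at alpha=0.05 for the model to collapse fully, so the
        # intercept-only probability under the null is ~0.95^7 ~ 0.70
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(900 + seed)
            df = covariate_frame(rng)
            df["y"] = rng.normal(0, 1, len(df))
            res = backwards_stepwise(df, "y")
            hits += res.retained == []
        assert hits >= 28

    def test_marginality_never_violated(self, rng):
        for _ in range(10):
            df = covariate_frame(rng)
            df["y"] = (
                0.05 * df["MET_C"] * df["C_pct"] + rng.normal(0, 1.0, len(df))
            )
            res = backwards_stepwise(df, "y")
            for term in res.retained:
                parts = term.split(":")
                if len(parts) > 1:
                    for p in parts:
                        assert p in res.retained

    def test_interaction_truth_retains_constituents(self, rng):
        df = covariate_frame(rng, n=60)
        df["y"] = 0.2 * df["MET_C"] * df["C_pct"] + rng.normal(0, 1.0, len(df))
        res = backwards_stepwise(df, "y")
        assert "MET_C:C_pct" in res.retained
        assert "MET_C" in res.retained and "C_pct" in res.retained

    def test_trace_records_each_elimination(self, rng):
        df = covariate_frame(rng)
        df["y"] = rng.normal(0, 1, len(df))
        res = backwards_stepwise(df, "y")
        assert (res.trace["dropped"][:-1]).all() if len(res.trace) > 1 else True
        assert res.trace["step"].is_monotonic_increasing


class TestVarianceExplained:
    def test_identity_and_independence(self, rng):
        df = covariate_frame(rng, n=500)
        df["y"] = df["C_pct"]
        assert variance_explained(df, "y", "C_pct") == pytest.approx(1.0)
        df["z"] = rng.normal(0, 1, len(df))
        assert variance_explained(df, "z", "C_pct") < 0.05

    def test_equals_squared_pearson_correlation(self, rng):
        df = covariate_frame(rng)
        df["y"] = 0.5 * df["MET_C"] + rng.normal(0, 4, len(df))
        r = np.corrcoef(df["MET_C"], df["y"])[0, 1]
        assert variance_explained(df, "y", "MET_C") == pytest.approx(r**2, rel=1e-12)

    def test_degenerate_covariate_rejected(self, rng):
        df = covariate_frame(rng)
        df["flat"] = 1.0
        df["y"] = rng.normal(0, 1, len(df))
        with pytest.raises(ValueError):
            variance_explained(df, "y", "flat")


def one_way_frame(rng, a=4, n=6, group_sd=2.0, resid_sd=1.0):
    rows = []
    for g in range(a):
        off = rng.normal(0, group_sd)
        for _ in range(n):
            rows.append({"transect": f"g{g}", "y": 3.0 + off + rng.normal(0, resid_sd)})
    return pd.DataFrame(rows)


class TestRandomIntercept:
    def test_balanced_ml_matches_closed_form(self, rng):
        df = one_way_frame(rng)
        res = lmm_random_intercept(df, "y", "1")
        a = df["transect"].nunique()
        n = len(df) // a
        grand = df["y"].mean()
        gm = df.groupby("transect")["y"].mean()
        sse = float(((df["y"] - df["transect"].map(gm)) ** 2).sum())
        ssb = float((n * (gm - grand) ** 2).sum())
        sigma_e = sse / (a * (n - 1))
        sigma_a = max((ssb / a - sigma_e) / n, 0.0)
        assert res.sigma2_within == pytest.approx(sigma_e, rel=1e-6)
        assert res.sigma2_between == pytest.approx(sigma_a, rel=1e-6)
        assert res.fe_params.iloc[0] == pytest.approx(grand, rel=1e-9)

    def test_matches_statsmodels_mixedlm_likelihood(self, rng):
        import statsmodels.formula.api as smf

        df = one_way_frame(rng, a=5, n=8)
        df["x"] = rng.uniform(0, 1, len(df))
        df["y"] = df["y"] + 1.5 * df["x"]
        ours = lmm_random_intercept(df, "y", "x")
        sm_fit = smf.mixedlm("y ~ x", df, groups=df["transect"]).fit(reml=False)
        assert ours.loglik >= float(sm_fit.llf) - 1e-4
        assert ours.fe_params["x"] == pytest.approx(float(sm_fit.fe_params["x"]), rel=1e-3)

    def test_no_between_variance_rarely_favours_random_effect(self):
        favoured = 0
        for seed in range(50):
            rng = np.random.default_rng(4200 + seed)
            df = one_way_frame(rng, group_sd=0.0)
            cmp_ = compare_random_intercept(df, "y", "1")
            favoured += cmp_.improved
        assert favoured <= 7  # AICc should reject the extra variance ≥85% of runs

    def test_strong_grouping_favours_random_effect(self):
        favoured = 0
        for seed in range(50):
            rng = np.random.default_rng(7700 + seed)
            df = one_way_frame(rng, group_sd=5.0, resid_sd=1.0)
            cmp_ = compare_random_intercept(df, "y", "1")
            favoured += cmp_.improved
        assert favoured >= 48

    def test_single_group_rejected(self, rng):
        df = one_way_frame(rng, a=1)
        with pytest.raises(ValueError):
            lmm_random_intercept(df, "y", "1")
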