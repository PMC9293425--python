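"""Synthetic study generator: design, covariates, traits, incubations."""

import io

import numpy as np
import pandas as pd
import pytest

from thermoresp import (
    DesignSpec,
    EnvironmentModel,
    IncubationProtocol,
    MMRTParams,
    TraitModel,
    assign_true_params,
    build_curves,
    generate_design,
    generate_environment,
    inject_dead_sample,
    simulate_incubations,
    simulate_study,
    t_opt,
)
from thermoresp import datasets
from thermoresp.respiration import frame_to_records


def zero_noise_env():
    return EnvironmentModel(met_transect_sd=0.0, met_within_sd=0.0, ph_sd=0.0,
                            c_log_sd=0.0, cn_sds={"grassland": 0.0, "kanuka": 0.0})


class TestDesign:
    def test_default_full_factorial(self):
        design = generate_design(DesignSpec())
        assert len(design) == 36
        assert design["point_id"].is_unique
        assert len(DesignSpec().incubation_temps_C) == 22

    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            ({"n_transects": 2}, 24),
            ({"n_transects": 1, "distances_m": (2,), "biomes": ("grassland",),
              "depths": ("0-50 mm",)}, 1),
        ],
    )
    def test_factor_counts(self, kwargs, expected):
        assert len(generate_design(DesignSpec(**kwargs))) == expected

    def test_invalid_temperature_grid_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec(incubation_temps_C=(10.0, 10.0, 12.0))


class TestEnvironment:
    def test_zero_noise_reproduces_anchor_means(self):
        pts = generate_environment(generate_design(), zero_noise_env(), seed=0)
        cell = pts[(pts.biome == "grassland") & (pts.depth == "0-50 mm") & (pts.distance_m == 30)]
        assert np.allclose(cell["MET_C"], 16.9)
        cell = pts[(pts.biome == "kanuka") & (pts.depth == "50-100 mm") & (pts.distance_m == 2)]
        assert np.allclose(cell["MET_C"], 48.3)

    def test_met_decreases_with_distance_within_series(self):
        pts = generate_environment(generate_design(), seed=7)
        for _, grp in pts.groupby(["transect", "biome", "depth"]):
            ordered = grp.sort_values("distance_m")["MET_C"].to_numpy()
            assert np.all(np.diff(ordered) < 0)

    def test_ph_negatively_correlated_with_met(self):
        pts = generate_environment(generate_design(), seed=3)
        assert np.corrcoef(pts["pH"], pts["MET_C"])[0, 1] < -0.3

    def test_flat_ph_slope_decouples_ph_from_met(self):
        model = EnvironmentModel(ph_met_slope=0.0, ph_sd=0.3,
                                 ph_intercepts={"grassland": 4.0, "kanuka": 4.0})
        corrs = [
            np.corrcoef(
                *generate_environment(generate_design(), model, seed=s)[["pH", "MET_C"]]
                .to_numpy().T
            )[0, 1]
            for s in range(1, 21)
        ]
        assert abs(np.mean(corrs)) < 0.15

    def test_met_span_exceeds_25_degrees(self):
        pts = generate_environment(generate_design(), seed=0)
        assert pts["MET_C"].max() - pts["MET_C"].min() > 25.0

    def test_carbon_nitrogen_positively_correlated(self):
        pts = generate_environment(generate_design(), seed=11)
        assert np.corrcoef(pts["C_pct"], pts["N_pct"])[0, 1] > 0.5

    def test_marginals_within_published_cell_envelope(self):
        env = datasets.environment_summary()
        for seed in (1, 2, 3):
            pts = generate_environment(generate_design(), seed=seed)
            for col in ("MET_C", "pH", "C_pct", "N_pct", "CN", "Ws_m3m3"):
                assert pts[col].min() >= env[col].min() - 1e-9
                assert pts[col].max() <= env[col].max() + 1e-9


class TestTrueParams:
    def test_trait_inversion_round_trip(self):
        pts = generate_environment(generate_design(), seed=0)
        pts = assign_true_params(pts, TraitModel(), seed=0)
        for _, row in pts.head(8).iterrows():
            p = MMRTParams(row["true_dH0_J_mol"], row["true_dCp_J_mol_K"], row["true_dS0_J_mol_K"])
            assert t_opt(p) - 273.15 == pytest.approx(row["true_T_opt_C"], rel=1e-9)

    def test_carbon_slope_controls_topt_difference(self):
        pts = generate_environment(generate_design(), zero_noise_env(), seed=0)
        pts = pts.head(2).copy()
        pts["C_pct"] = [5.0, 15.0]
        pts["MET_C"] = 20.0
        model = TraitModel(topt_sd=0.0, lnr25_sd=0.0)
        pts = assign_true_params(pts, model, seed=0)
        dT = pts["true_T_opt_C"].iloc[1] - pts["true_T_opt_C"].iloc[0]
        assert dT == pytest.approx(13.0, abs=1e-9)

    def test_zero_slopes_and_noise_give_identical_topt(self):
        pts = generate_environment(generate_design(), seed=0)
        model = TraitModel(topt_C_slope=0.0, topt_MET_slope=0.0, topt_sd=0.0)
        pts = assign_true_params(pts, model, seed=0)
        assert pts["true_T_opt_C"].nunique() == 1

    def test_all_heat_capacities_below_minus_R(self):
        pts = assign_true_params(generate_environment(generate_design(), seed=0), seed=0)
        assert (pts["true_dCp_J_mol_K"] < -8.314).all()


class TestIncubations:
    def test_default_counts(self):
        points, incubations, _ = simulate_study(seed=0)
        assert len(points) == 36
        assert len(incubations) == 792
        # two CO2 readings (initial + final) per incubation
        assert incubations[["initial_ppm", "final_ppm"]].size == 1584

    def test_durations_within_protocol_window(self):
        _, incubations, _ = simulate_study(seed=4)
        assert incubations["duration_min"].between(52.0, 169.0).all()

    def test_byte_for_byte_determinism(self):
        frames1 = simulate_study(seed=12)
        frames2 = simulate_study(seed=12)
        for a, b in zip(frames1[:2], frames2[:2]):
            buf_a, buf_b = io.StringIO(), io.StringIO()
            a.to_csv(buf_a, index=False)
            b.to_csv(buf_b, index=False)
            assert buf_a.getvalue() == buf_b.getvalue()
        assert frames1[2] == frames2[2]

    def test_seed_changes_output(self):
        a = simulate_study(seed=1)[1]
        b = simulate_study(seed=2)[1]
        assert not a.equals(b)

    def test_noiseless_rates_recover_truth_exactly(self):
        spec = DesignSpec(n_transects=1)
        pts = generate_environment(generate_design(spec), seed=0)
        pts = assign_true_params(pts, TraitModel(), seed=0)
        protocol = IncubationProtocol(temp_sd_C=0.0, initial_ppm_sd=0.0)
        inc = simulate_incubations(pts, spec, protocol, rate_log_sd=0.0, seed=0)
        from thermoresp import mmrt_log_rate, respiration_rate

        by_id = {row["point_id"]: row for _, row in pts.iterrows()}
        for rec in frame_to_records(inc)[:40]:
            row = by_id[rec.sample_id]
            p = MMRTParams(row["true_dH0_J_mol"], row["true_dCp_J_mol_K"], row["true_dS0_J_mol_K"])
            expected = np.exp(mmrt_log_rate(p, rec.measured_T_C + 273.15))
            assert respiration_rate(rec) == pytest.approx(expected, rel=1e-10)


class TestDeadSample:
    def test_injection_silences_one_shrubland_sample(self):
        _, inc, dead_id = simulate_study(seed=0, dead_sample=True)
        assert "kanuka" in dead_id
        sub = inc[inc.sample_id == dead_id]
        assert (sub["final_ppm"] == sub["initial_ppm"]).all()

    def test_discard_count_matches_field_study(self):
        _, inc, _ = simulate_study(seed=0, dead_sample=True)
        _, counts = build_curves(frame_to_records(inc))
        assert counts == {"kept": 35, "discarded": 1}

    def test_idempotent(self):
        _, inc, dead_id = simulate_study(seed=0, dead_sample=True)
        again, chosen = inject_dead_sample(inc, sample_id=dead_id)
        assert chosen == dead_id
        pd.testing.assert_frame_equal(again, inc)

    def test_unknown_sample_rejected(self):
        _, inc, _ = simulate_study(seed=0, dead_sample=False)
        with pytest.raises(ValueError, match="unknown sample"):
            inject_dead_sample(inc, sample_id="nope")

    def test_single_point_design_leaves_nothing_fittable(self):
        spec = DesignSpec(n_transects=1, distances_m=(2,), biomes=("kanuka",),
                          depths=("0-50 mm",))
        pts = assign_true_params(
            generate_environment(generate_design(spec), seed=0), seed=0
        )
        inc = simulate_incubations(pts, spec, seed=0)
        inc, _ = inject_dead_sample(inc)
        _, counts = build_curves(frame_to_records(inc))
        assert counts["kept"] == 0
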