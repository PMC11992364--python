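"""Binning, joint fitting, sink prediction and recovery experiments."""

import numpy as np
import pandas as pd
import pytest

from pherograd import (
    GradientShape,
    NoiseConfig,
    PopulationConfig,
    ResponseParams,
    bin_cells,
    generate_dataset,
    joint_fit,
    normalize_profile,
    observed_response,
    orientation_enrichment,
    predict_sink_response,
    recovery_experiment,
    simulate_gfp,
    simulate_length,
)
from pherograd.fit import FitResult


def _receiver_frame(x, **columns):
    x = np.asarray(x, dtype=float)
    base = {
        "cell_id": [f"c{i}" for i in range(len(x))],
        "identity": "receiver",
        "x_um": x,
        "area_px": np.nan,
        "gfp_au": np.nan,
        "length_um": np.nan,
        "orientation_deg": np.nan,
    }
    base.update(columns)
    return pd.DataFrame(base)


def _center_aligned_noiseless(shape, resp_g, resp_m):
    """Noiseless cells placed exactly at retained-bin centers; one anchor
    cell pins the leftmost bin edge and is discarded by the default trim."""
    x = np.r_[-2700.0, np.arange(-2550.0, 2700.0, 100.0)]
    rec = _receiver_frame(x)
    rng = np.random.default_rng(0)
    quiet = NoiseConfig(gfp_cv=0.0, length_sd=0.0)
    rec = simulate_gfp(rec, shape, resp_g, quiet, rng)
    rec = simulate_length(rec, shape, resp_m, quiet, rng)
    return rec


class TestBinCells:
    def test_study_scale_bin_count(self, noisy_dataset):
        # ≈6,700 receivers over 5,400 μm at 100-μm bins, one bin trimmed
        prof = bin_cells(noisy_dataset, "gfp")
        assert len(prof.bin_centers) == 53
        assert prof.counts.sum() > 6000

    def test_singleton_bin(self):
        rec = _receiver_frame([0.0, 250.0], gfp_au=[1.0, 3.0])
        prof = bin_cells(rec, "gfp", width=100.0, trim_left=0.0)
        assert list(prof.counts) == [1, 1]
        assert list(prof.sems) == [0.0, 0.0]
        assert prof.means[0] == 1.0

    def test_trim_left_drops_margin_bins(self):
        rec = _receiver_frame(np.arange(0.0, 1000.0, 10.0),
                              gfp_au=np.ones(100))
        full = bin_cells(rec, "gfp", width=100.0, trim_left=0.0)
        trimmed = bin_cells(rec, "gfp", width=100.0, trim_left=100.0)
        assert len(full.bin_centers) - len(trimmed.bin_centers) == 1
        assert trimmed.bin_centers[0] > full.bin_centers[0]

    def test_binning_bias(self, study_shape, resp_g, resp_m):
        # noiseless cells on a dense regular grid isolate pure binning bias
        # (cell-averaged bin vs model at the bin center). The Michaelian
        # channel stays below 0.5%; the switch-like n = 3 channel is more
        # curved near the border (log-divergent concentration slope) and
        # carries a larger, still small, bias there.
        from pherograd.simulate import NoiseConfig as NC

        x = np.arange(-2700.0, 2700.0, 1.0) + 0.5
        rec = _receiver_frame(x)
        rng = np.random.default_rng(0)
        quiet = NC(gfp_cv=0.0, length_sd=0.0)
        rec = simulate_gfp(rec, study_shape, resp_g, quiet, rng)
        rec = simulate_length(rec, study_shape, resp_m, quiet, rng)
        for channel, resp, bound in (
            ("gfp", resp_g, 0.005),
            ("length", resp_m, 0.02),
        ):
            prof = bin_cells(rec, channel, trim_left=0.0)
            model = observed_response(prof.bin_centers, study_shape, resp)
            rel = np.abs(prof.means - model) / model
            assert np.max(rel) < bound

    def test_errors(self):
        rec = _receiver_frame([1.0], gfp_au=[np.nan])
        with pytest.raises(ValueError):
            bin_cells(rec, "gfp")
        with pytest.raises(ValueError, match="channel"):
            bin_cells(_receiver_frame([1.0], gfp_au=[1.0]), "cyan")


class TestJointFit:
    def test_noiseless_self_consistency(self, study_shape, resp_g, resp_m):
        rec = _center_aligned_noiseless(study_shape, resp_g, resp_m)
        fit = joint_fit(bin_cells(rec, "gfp"), bin_cells(rec, "length"))
        assert fit.n_m == 3
        assert fit.lambda_ == pytest.approx(735.0, rel=1e-4)
        assert fit.C == pytest.approx(1.45, rel=1e-4)
        assert fit.A_g == pytest.approx(1.0, rel=1e-4)
        assert fit.b_g == pytest.approx(0.1, abs=1e-4)
        assert fit.A_m == pytest.approx(25.0, rel=1e-4)
        assert fit.b_m == pytest.approx(5.0, rel=1e-4)
        assert len(fit.sse_by_n) == 7
        assert fit.sse_total == min(fit.sse_by_n.values())

    def test_flat_morphology_is_degenerate(self, study_shape, resp_g):
        flat = ResponseParams(n=1, A=0.0, b=5.0)
        df = generate_dataset(
            PopulationConfig(n_receivers=3000, n_emitters=0),
            study_shape, resp_g, flat,
            NoiseConfig(gfp_cv=0.3, length_sd=0.0), seed=8,
        )
        fit = joint_fit(bin_cells(df, "gfp"), bin_cells(df, "length"))
        assert fit.diagnostics["n_degenerate"]
        assert fit.A_m < 1e-4

    def test_shuffling_morphology_degrades_lambda(
        self, study_shape, resp_g, resp_m, study_pop, default_noise
    ):
        df = generate_dataset(study_pop, study_shape, resp_g, resp_m,
                              default_noise, seed=5)
        gfp = bin_cells(df, "gfp")
        fit = joint_fit(gfp, bin_cells(df, "length"))

        shuffled = df.copy()
        rec = shuffled.identity == "receiver"
        vals = shuffled.loc[rec, "length_um"].to_numpy().copy()
        np.random.default_rng(99).shuffle(vals)
        shuffled.loc[rec, "length_um"] = vals
        fit_shuffled = joint_fit(gfp, bin_cells(shuffled, "length"))

        assert abs(fit.lambda_ - 735.0) < abs(fit_shuffled.lambda_ - 735.0)

    def test_diagnostics_keys(self, study_shape, resp_g, resp_m):
        rec = _center_aligned_noiseless(study_shape, resp_g, resp_m)
        fit = joint_fit(bin_cells(rec, "gfp"), bin_cells(rec, "length"))
        for key in ("lambda_at_bound", "C_at_bound", "n_degenerate"):
            assert fit.diagnostics[key] is False


class TestNormalizeProfile:
    def test_plateau_bins_near_theoretical_maximum(
        self, noisy_dataset, resp_m, study_shape
    ):
        prof = bin_cells(noisy_dataset, "length")
        norm = normalize_profile(prof, resp_m)
        plateau = study_shape.C ** 3 / (1 + study_shape.C ** 3)
        leftmost = norm.means[:5] / plateau
        assert np.all(np.abs(leftmost - 1.0) < 0.1)

    def test_round_trip_identity(self, noisy_dataset, resp_m):
        prof = bin_cells(noisy_dataset, "length")
        norm = normalize_profile(prof, resp_m)
        back = norm.means * resp_m.A + resp_m.b
        np.testing.assert_allclose(back, prof.means, rtol=1e-12)
        np.testing.assert_allclose(norm.sems * resp_m.A, prof.sems,
                                   rtol=1e-12)

    def test_amplitude_error(self, noisy_dataset):
        prof = bin_cells(noisy_dataset, "length")
        with pytest.raises(ValueError):
            normalize_profile(prof, ResponseParams(n=3, A=0.0, b=5.0))


class TestPredictSink:
    @pytest.fixture()
    def source_fit(self, study_shape, resp_g, resp_m):
        rec = _center_aligned_noiseless(study_shape, resp_g, resp_m)
        return joint_fit(bin_cells(rec, "gfp"), bin_cells(rec, "length"))

    def test_flat_at_baseline_in_sink_domain(self, source_fit):
        x = np.linspace(1.0, 5000.0, 50)
        pred = predict_sink_response(source_fit, x)
        np.testing.assert_allclose(pred, source_fit.b_m, rtol=1e-9)

    def test_far_field_plateau_matches_source(self, source_fit, study_shape,
                                              resp_m):
        pred = predict_sink_response(source_fit, np.array([-1e9]))[0]
        source_plateau = observed_response(-1e9, study_shape, resp_m)
        assert pred == pytest.approx(source_plateau, rel=1e-3)

    def test_equals_response_of_reflected_source_profile(
        self, source_fit, study_shape
    ):
        from pherograd import source_profile, hill_response

        x = -np.geomspace(1.0, 3000.0, 40)
        pred = predict_sink_response(source_fit, x)
        f = np.asarray(source_profile(x, source_fit.lambda_))
        expected = source_fit.A_m * np.asarray(
            hill_response(source_fit.C * (2 * f - 1), source_fit.n_m)
        ) + source_fit.b_m
        np.testing.assert_allclose(pred, expected, rtol=1e-12)

    def test_matches_synthetic_sink_data_within_noise(
        self, source_fit, study_shape, resp_g, resp_m, default_noise
    ):
        df = generate_dataset(
            PopulationConfig(), study_shape, resp_g, resp_m, default_noise,
            seed=31, geometry="sink",
        )
        prof = bin_cells(df, "length")
        pred = predict_sink_response(source_fit, prof.bin_centers)
        sems = np.where(prof.sems > 0, prof.sems, prof.sems.max())
        within = np.abs(pred - prof.means) < 4 * sems
        assert within.mean() > 0.9


class TestRecoveryExperiment:
    def test_small_recovery_run(self, study_shape, resp_g, resp_m):
        res = recovery_experiment(
            study_shape, resp_g, resp_m,
            PopulationConfig(n_receivers=1500, n_emitters=0),
            NoiseConfig(), n_seeds=3, base_seed=11,
        )
        assert len(res["per_seed"]) == 3
        assert not res["failures"]
        assert set(res["summary"]["parameter"]) == {
            "lambda_", "C", "A_g", "b_g", "A_m", "b_m"
        }
        lam_row = res["summary"].set_index("parameter").loc["lambda_"]
        assert abs(lam_row["bias"]) < 300.0

    def test_more_cells_tighten_lambda(self, study_shape, resp_g, resp_m):
        def rmse(n):
            res = recovery_experiment(
                study_shape, resp_g, resp_m,
                PopulationConfig(n_receivers=n, n_emitters=0),
                NoiseConfig(), n_seeds=3, base_seed=11,
            )
            return res["summary"].set_index("parameter").loc["lambda_", "rmse"]

        assert rmse(6400) < rmse(800)

    def test_requires_multiple_seeds(self, study_shape, resp_g, resp_m):
        with pytest.raises(ValueError):
            recovery_experiment(study_shape, resp_g, resp_m,
                                PopulationConfig(), NoiseConfig(), n_seeds=1)


class TestOrientationEnrichment:
    def test_uniform_sample_not_significant(self, noisy_dataset):
        res = orientation_enrichment(noisy_dataset, area_cutoff=200.0)
        assert res["n"] >= 20
        assert res["pvalue"] > 0.01

    def test_aligned_sample_detected(self):
        rng = np.random.default_rng(17)
        n = 300
        rec = _receiver_frame(
            np.linspace(-2000, -100, n),
            area_px=np.full(n, 500.0),
            orientation_deg=rng.uniform(0.0, 10.0, n),
        )
        res = orientation_enrichment(rec, area_cutoff=200.0)
        assert res["pvalue"] < 0.01

    def test_cutoff_excludes_everything(self, noisy_dataset):
        with pytest.raises(ValueError, match="at least 20"):
            orientation_enrichment(noisy_dataset, area_cutoff=1e9)


class TestFitResultContainer:
    def test_shape_and_response_views(self):
        fit = FitResult(lambda_=700.0, C=1.4, A_g=1.0, b_g=0.1, A_m=25.0,
                        b_m=5.0, n_m=3, sse_total=0.0,
                        sse_by_n={n: 0.0 for n in range(1, 8)})
        assert isinstance(fit.shape, GradientShape)
        assert fit.resp_m.n == 3
        assert fit.resp_g.n == 1
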