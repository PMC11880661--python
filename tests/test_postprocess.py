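import numpy as np
import pandas as pd
import pytest

from covrn.postprocess import (
    SchemaError,
    posterior_predictive,
    predict_correlation,
    recovery_report,
    sweep_correlation,
)


class TestPredictCorrelation:
    def test_draws_match_link_algebra(self, tiny_fit):
        _, _, model, result = tiny_fit
        grid = pd.DataFrame({"climate": np.linspace(-2, 2, 9)})
        curve = predict_correlation(result, model, grid)
        st = model.standardization["contexts.climate"]
        x = (grid["climate"].to_numpy() - st["mean"]) / st["sd"]
        b0 = np.ravel(result.draws["br_intercept"])
        b1 = np.ravel(result.draws["br_climate"])
        expected = np.tanh(b0[:, None] + b1[:, None] * x[None, :])
        np.testing.assert_allclose(curve.r_draws, expected, atol=1e-12)

    def test_all_draws_strictly_inside_unit_interval(self, tiny_fit):
        _, _, model, result = tiny_fit
        curve = sweep_correlation(result, model, "climate")
        assert np.all(np.abs(curve.r_draws) < 1.0)

    def test_bands_nested_and_ordered(self, tiny_fit):
        _, _, model, result = tiny_fit
        frame = sweep_correlation(result, model, "climate").frame()
        assert (frame["r_lo89"] <= frame["r_lo50"]).all()
        assert (frame["r_lo50"] <= frame["r_median"]).all()
        assert (frame["r_median"] <= frame["r_hi50"]).all()
        assert (frame["r_hi50"] <= frame["r_hi89"]).all()

    def test_positive_slope_draws_are_monotone(self, tiny_fit):
        _, _, model, result = tiny_fit
        curve = sweep_correlation(result, model, "climate", n_points=20)
        slopes = np.ravel(result.draws["br_climate"])
        rising = curve.r_draws[slopes > 0]
        assert np.all(np.diff(rising, axis=1) > 0)

    def test_fitted_contexts_self_consistency(self, tiny_fit):
        ds, gt, model, result = tiny_fit
        curve = predict_correlation(result, model, ds.contexts[["climate"]])
        med = np.median(curve.r_draws, axis=0)
        # medians should track the generating correlations loosely
        assert np.corrcoef(med, gt.r_context["r"])[0, 1] > 0.8

    def test_affine_recoding_invariance(self, tiny_fit):
        # predicting at x and at the recoded 2x + 3 with a consistently
        # recoded standardization yields identical correlations
        _, _, model, result = tiny_fit
        grid = pd.DataFrame({"climate": np.linspace(-1, 1, 5)})
        base = predict_correlation(result, model, grid).r_draws
        st = model.standardization["contexts.climate"]
        saved = dict(st)
        try:
            st["mean"] = saved["mean"] * 2.0 + 3.0
            st["sd"] = saved["sd"] * 2.0
            recoded = predict_correlation(
                result, model, pd.DataFrame({"climate": grid["climate"] * 2.0 + 3.0})
            ).r_draws
        finally:
            st.update(saved)
        np.testing.assert_allclose(recoded, base, atol=1e-12)

    def test_column_mismatch_rejected(self, tiny_fit):
        _, _, model, result = tiny_fit
        with pytest.raises(SchemaError, match="missing"):
            predict_correlation(result, model, pd.DataFrame({"snow": [0.0]}))

    def test_unknown_sweep_covariate(self, tiny_fit):
        _, _, model, result = tiny_fit
        with pytest.raises(SchemaError):
            sweep_correlation(result, model, "density")

    def test_curve_csv(self, tiny_fit, tmp_path):
        _, _, model, result = tiny_fit
        path = tmp_path / "curve.csv"
        sweep_correlation(result, model, "climate", n_points=7).to_csv(path)
        back = pd.read_csv(path)
        assert len(back) == 7
        assert {"climate", "r_mean", "r_median", "r_lo50", "r_hi89"} <= set(back.columns)

    def test_observation_level_labelling(self, tiny_fit):
        _, _, model, result = tiny_fit
        curve = sweep_correlation(result, model, "climate")
        assert curve.level_label == "observation"


class TestPosteriorPredictive:
    def test_one_replicate_per_draw(self, tiny_fit):
        _, _, model, result = tiny_fit
        n_avail = result.raw_top.shape[0] * result.raw_top.shape[1]
        report = posterior_predictive(result, model, n_reps=n_avail, seed=1)
        for trait in report.replicated.values():
            for stat in trait.values():
                assert stat.shape == (n_avail,)

    def test_too_many_reps_rejected(self, tiny_fit):
        _, _, model, result = tiny_fit
        n_avail = result.raw_top.shape[0] * result.raw_top.shape[1]
        with pytest.raises(ValueError, match="subsample"):
            posterior_predictive(result, model, n_reps=n_avail + 1)

    def test_well_specified_model_calibrated(self, tiny_fit):
        _, _, model, result = tiny_fit
        report = posterior_predictive(result, model, n_reps=300, seed=3)
        for trait in report.observed:
            for stat in ("mean", "sd"):
                p = report.tail_probability(trait, stat)
                assert 0.01 < p < 0.99, f"{trait}/{stat} tail probability {p}"

    def test_count_histogram_present(self, tiny_fit):
        _, _, model, result = tiny_fit
        report = posterior_predictive(result, model, n_reps=50, seed=2)
        assert "fecundity" in report.histograms
        hist = report.histograms["fecundity"]
        assert hist["observed"].sum() == len(model.t2.y)

    def test_frame_and_csv(self, tiny_fit, tmp_path):
        _, _, model, result = tiny_fit
        report = posterior_predictive(result, model, n_reps=50, seed=2)
        frame = report.frame()
        assert set(frame["statistic"]) == {"mean", "sd"}
        report.to_csv(tmp_path / "ppc.csv")
        assert (tmp_path / "ppc.csv").exists()

    def test_misspecification_detected(self, tiny_fit):
        # inflate observed counts far beyond the fitted model: the SD tail
        # probability for the count trait must go extreme
        _, _, model, result = tiny_fit
        inflated = model.t2.y.copy()
        original = model.t2.y
        try:
            rng = np.random.default_rng(0)
            model.t2.y = original + (rng.random(original.shape) < 0.1) * 15
            report = posterior_predictive(result, model, n_reps=200, seed=4)
            p = report.tail_probability(model.trait_names[1], "sd")
            assert p < 0.01 or p > 0.99
        finally:
            model.t2.y = original


class _MockGT:
    def __init__(self, truth):
        self.param_truth = truth


def _mock_result(draw_values):
    from covrn.inference import MCMCConfig, PosteriorResult

    draws = {k: np.asarray(v, dtype=float).reshape(1, -1) for k, v in draw_values.items()}
    return PosteriorResult(
        draws=draws, draws_raw=draws, rhat={k: 1.0 for k in draws},
        diagnostics={"divergences": [0]}, config=MCMCConfig(n_chains=1, seed=0),
    )


class TestRecoveryReport:
    def test_point_mass_posterior_fully_covered(self):
        result = _mock_result({"br_intercept": [0.3] * 10, "br_climate": [0.6] * 10})
        gt = _MockGT({"br_intercept": 0.3, "br_climate": 0.6})
        table = recovery_report(gt, result)
        assert table["covered50"].all()
        assert table["covered89"].all()
        assert (table["hi89"] - table["lo89"] == 0).all()

    def test_shifted_posterior_not_covered(self):
        rng = np.random.default_rng(0)
        result = _mock_result({"br_climate": rng.normal(2.0, 0.01, 500)})
        table = recovery_report(_MockGT({"br_climate": 0.6}), result)
        assert not table.loc["br_climate", "covered89"]

    def test_unmapped_parameter_raises(self):
        result = _mock_result({"br_intercept": [0.0]})
        with pytest.raises(KeyError, match="no_such_param"):
            recovery_report(_MockGT({"no_such_param": 1.0}), result)

    def test_real_fit_report_structure(self, tiny_fit):
        _, gt, _, result = tiny_fit
        table = recovery_report(gt, result)
        assert set(table.index) == set(gt.param_truth)
        assert {"truth", "posterior_mean", "lo89", "hi89", "covered89"} <= set(table.columns)
        # a healthy fit covers most generating parameters
        assert table["covered89"].sum() >= len(table) - 2


class TestTruthCalibration:
    def test_tail_probabilities_uniformish_across_seeds(self):
        # replicate statistics computed with the generating parameters on
        # the simulator's own output: upper-tail probabilities should be
        # spread over (0, 1) rather than piling at the extremes
        from covrn.modelspec import build_model, spec_for_dataset
        from covrn.simulate import SimConfig, simulate_intraindividual

        probs = {"mean": [], "sd": []}
        for seed in range(20):
            cfg = SimConfig(n_years=5, recruits_per_year=12, seed=seed)
            ds, gt = simulate_intraindividual(cfg)
            model = build_model(spec_for_dataset(ds), ds)
            theta = np.zeros(model.n_params)
            # generating values mapped into the standardized coordinates
            st1 = model.standardization["trait1.climate"]
            st3 = model.standardization["contexts.climate"]
            tr = gt.param_truth
            theta[model.sl["b1"]] = [
                tr["b1_intercept"] + tr["b1_climate"] * st1["mean"],
                tr["b1_climate"] * st1["sd"],
            ]
            st2 = model.standardization["trait2.climate"]
            theta[model.sl["b2"]] = [
                tr["b2_intercept"] + tr["b2_climate"] * st2["mean"],
                tr["b2_climate"] * st2["sd"],
            ]
            theta[model.sl["br"]] = [
                tr["br_intercept"] + tr["br_climate"] * st3["mean"],
                tr["br_climate"] * st3["sd"],
            ]
            theta[model.sl["log_sd"]] = np.log([tr["sd_o1"], tr["sd_o2"]])
            rng = np.random.default_rng(seed + 1000)
            reps = [model.simulate_replicate(rng, theta) for _ in range(40)]
            for stat, f in (("mean", np.mean), ("sd", lambda v: np.std(v, ddof=1))):
                obs = f(model.t1.y)
                rep = np.array([f(r[0]) for r in reps])
                probs[stat].append(float(np.mean(rep >= obs)))
        for stat, p in probs.items():
            p = np.asarray(p)
            assert 0.25 < p.mean() < 0.75, (stat, p)
            assert p.max() - p.min() > 0.3, (stat, p)
            assert np.sum((p < 0.02) | (p > 0.98)) <= 5, (stat, p)
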