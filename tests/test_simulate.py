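import numpy as np
import pandas as pd
import pytest

from covrn.linkbias import corr_link
from covrn.simulate import (
    SimConfig,
    simulate_intergenerational,
    simulate_intraindividual,
    simulate_marmot_like,
    simulate_sheep_like,
    ztp_baseline_log_rate,
    _zero_truncated_poisson,
)

ALL_SIMS = [
    simulate_intergenerational,
    simulate_intraindividual,
    simulate_marmot_like,
    simulate_sheep_like,
]


class TestConfig:
    def test_defaults_match_validation_setup(self):
        cfg = SimConfig()
        assert cfg.n_years == 30
        assert cfg.recruits_per_year == 25
        assert cfg.mean_fecundity == 2.5
        assert cfg.annual_survival == 0.6
        assert cfg.total_recruits == 750

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_years": 0},
            {"annual_survival": 1.2},
            {"mean_fecundity": -1.0},
            {"sd_o1": 0.0},
            {"climate_dist": [0.0, 1.0]},  # wrong length for 30 years
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestDemography:
    @pytest.mark.parametrize("sim", ALL_SIMS)
    def test_total_individuals_is_years_times_recruits(self, sim):
        ds, _ = sim(SimConfig(n_years=10, recruits_per_year=7, seed=2))
        inds = set(ds.trait1["individual"]) | set(ds.trait2["individual"])
        assert len(inds) == 70

    def test_paper_dimensions_750_individuals(self):
        for sim in (simulate_intergenerational, simulate_intraindividual):
            ds, _ = sim(SimConfig(seed=9))
            assert ds.trait2["individual"].nunique() == 750

    def test_zero_survival_single_year_lifespans(self):
        ds, _ = simulate_intraindividual(
            SimConfig(n_years=5, recruits_per_year=20, annual_survival=0.0, seed=1)
        )
        spans = ds.trait1.groupby("individual")["context"].nunique()
        assert (spans == 1).all()

    def test_lifespans_are_contiguous_year_runs(self):
        ds, _ = simulate_intraindividual(SimConfig(n_years=12, recruits_per_year=10, seed=5))
        year_of = {c: i for i, c in enumerate(sorted(ds.contexts["context"]))}
        for _, grp in ds.trait1.groupby("individual"):
            ys = sorted(year_of[c] for c in grp["context"])
            assert ys == list(range(ys[0], ys[0] + len(ys)))

    def test_realized_survival_near_config(self):
        ds, _ = simulate_intraindividual(
            SimConfig(n_years=10, recruits_per_year=800, seed=3)
        )
        present = {
            y: set(g["individual"]) for y, g in ds.trait1.groupby("context")
        }
        years = sorted(present)
        fracs = [
            len(present[a] & present[b]) / len(present[a])
            for a, b in zip(years[:-1], years[1:])
        ]
        assert np.mean(fracs) == pytest.approx(0.6, abs=0.02)


class TestDeterminism:
    @pytest.mark.parametrize("sim", ALL_SIMS)
    def test_identical_seed_identical_dataset(self, sim):
        cfg = SimConfig(n_years=5, recruits_per_year=6, seed=13)
        a, _ = sim(cfg)
        b, _ = sim(cfg)
        pd.testing.assert_frame_equal(a.trait1, b.trait1)
        pd.testing.assert_frame_equal(a.trait2, b.trait2)
        pd.testing.assert_frame_equal(a.contexts, b.contexts)

    def test_written_files_byte_identical(self, tmp_path):
        cfg = SimConfig(n_years=4, recruits_per_year=5, seed=21)
        for d in ("a", "b"):
            ds, _ = simulate_intergenerational(cfg)
            ds.write(tmp_path / d)
        for f in ("trait1.csv", "trait2.csv", "contexts.csv", "metadata.yaml"):
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_different_seeds_differ(self):
        a, _ = simulate_intraindividual(SimConfig(n_years=4, recruits_per_year=5, seed=1))
        b, _ = simulate_intraindividual(SimConfig(n_years=4, recruits_per_year=5, seed=2))
        assert not a.trait1["value"].equals(b.trait1["value"])


class TestInjectedCorrelation:
    def test_no_correlation_when_beta_r_zero(self):
        _, gt = simulate_intraindividual(
            SimConfig(n_years=4, recruits_per_year=2000, annual_survival=0.0,
                      beta_r=(0.0, 0.0), seed=8)
        )
        r = np.corrcoef(gt.latents["o1"], gt.latents["o2"])[0, 1]
        assert abs(r) < 0.03

    def test_two_fixed_climates_give_tanh_of_pm_one(self):
        cfg = SimConfig(
            n_years=2,
            recruits_per_year=5000,
            annual_survival=0.0,
            beta_r=(0.0, 1.0),
            climate_dist=[1.0, -1.0],
            seed=6,
        )
        _, gt = simulate_intergenerational(cfg)
        lat = gt.latents.merge(gt.climate, on="context")
        for clim in (1.0, -1.0):
            sub = lat[lat["climate"] == clim]
            r = np.corrcoef(sub["o1"], sub["o2"])[0, 1]
            assert r == pytest.approx(np.tanh(clim), abs=0.03)

    def test_latent_slope_recovery_on_link_scale(self):
        # regression of atanh(per-year latent correlation) on climate
        cfg = SimConfig(
            n_years=30, recruits_per_year=5000, annual_survival=0.0,
            beta_r=(-0.2, 0.6), seed=10,
        )
        _, gt = simulate_intraindividual(cfg)
        lat = gt.latents.merge(gt.climate, on="context")
        rows = []
        for _, g in lat.groupby("context"):
            rows.append((g["climate"].iloc[0], np.corrcoef(g["o1"], g["o2"])[0, 1]))
        x = np.array([r[0] for r in rows])
        z = corr_link(np.array([r[1] for r in rows]))
        X = np.column_stack([np.ones_like(x), x])
        coef, res, *_ = np.linalg.lstsq(X, z, rcond=None)
        dof = len(x) - 2
        sigma2 = float(res[0]) / dof
        se_slope = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(coef[1] - 0.6) < 3 * se_slope
        assert coef[0] == pytest.approx(-0.2, abs=0.02)

    def test_ground_truth_r_is_tanh_of_linear_predictor(self):
        _, gt = simulate_intraindividual(SimConfig(n_years=6, recruits_per_year=5, seed=2))
        pred = np.tanh(
            gt.config.beta_r[0] + gt.config.beta_r[1] * gt.climate["climate"].to_numpy()
        )
        np.testing.assert_allclose(gt.r_context["r"].to_numpy(), pred, rtol=0, atol=1e-15)


class TestFamilies:
    def test_litter_sizes_are_positive_integers(self, interg_small):
        ds, _ = interg_small
        v = ds.trait2["value"]
        assert (v >= 1).all() and (v == v.round()).all()

    def test_fecundity_counts_nonnegative_integers(self, intra_small):
        ds, _ = intra_small
        v = ds.trait2["value"]
        assert (v >= 0).all() and (v == v.round()).all()

    def test_sheep_fecundity_in_ordinal_support(self, sheep_small):
        ds, _ = sheep_small
        assert set(ds.trait1["value"].unique()) <= {0, 1, 2}

    def test_saturated_thresholds(self):
        lo, _ = simulate_sheep_like(
            SimConfig(n_years=3, recruits_per_year=30, thresholds=(-40.0, -30.0), seed=1)
        )
        assert (lo.trait1["value"] == 2).all()
        hi, _ = simulate_sheep_like(
            SimConfig(n_years=3, recruits_per_year=30, thresholds=(30.0, 40.0), seed=1)
        )
        assert (hi.trait1["value"] == 0).all()

    def test_non_increasing_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            simulate_sheep_like(SimConfig(n_years=2, recruits_per_year=3, thresholds=(1.0, 1.0)))

    def test_hybrid_offspring_rows_match_litter_sizes(self, interg_small):
        ds, _ = interg_small
        per_pair = ds.trait1.groupby(["individual", "context"]).size()
        litters = ds.trait2.set_index(["individual", "context"])["value"]
        aligned = litters.loc[per_pair.index]
        assert (per_pair == aligned).all()


class TestFecundityCalibration:
    def test_ztp_sampler_matches_truncated_mean(self):
        rng = np.random.default_rng(0)
        lam = np.full(200_000, 1.7)
        draws = _zero_truncated_poisson(rng, lam)
        assert draws.min() >= 1
        expected = 1.7 / -np.expm1(-1.7)
        assert draws.mean() == pytest.approx(expected, abs=0.01)

    def test_baseline_rate_below_log_mean(self):
        a = ztp_baseline_log_rate(2.5, 0.3)
        assert a < np.log(2.5)

    def test_realized_mean_litter_at_baseline(self):
        cfg = SimConfig(n_years=4, recruits_per_year=3000, climate_dist=[0.0] * 4, seed=5)
        ds, _ = simulate_intergenerational(cfg)
        assert ds.trait2["value"].mean() == pytest.approx(2.5, abs=0.05)

    def test_mean_fecundity_at_most_one_rejected(self):
        with pytest.raises(ValueError, match="mean_fecundity"):
            ztp_baseline_log_rate(0.9, 0.3)


class TestMarmotLike:
    def test_schema(self, marmot_small):
        ds, _ = marmot_small
        for col in ("snow", "june_temp", "age", "age_sq", "mother_mass"):
            assert col in ds.trait1.columns
            assert col in ds.trait2.columns
        assert {"snow", "june_temp"} <= set(ds.contexts.columns)
        assert ds.design == "hybrid"

    def test_zero_effects_variance_partition(self):
        # with no covariate effects, a method-of-moments random-intercept
        # decomposition of mother-year mass means recovers the latent SDs
        effects = {
            "beta1": dict.fromkeys(["snow", "june_temp", "age", "age_sq", "mother_mass"], 0.0),
            "beta2": dict.fromkeys(["snow", "age", "age_sq", "mother_mass"], 0.0),
            "beta_r": (0.0, 0.0, 0.0),
            "sd_year1": 1e-9,
            "sd_year2": 1e-9,
        }
        cfg = SimConfig(n_years=10, recruits_per_year=600, sd_o1=0.5, sd_within=0.4, seed=3)
        ds, _ = simulate_marmot_like(cfg, effects=effects)
        grp = ds.trait1.groupby(["individual", "context"])["value"]
        n_i = grp.size().to_numpy()
        means = grp.mean().to_numpy()
        within = grp.var(ddof=1).dropna().mean()
        assert within == pytest.approx(0.4**2, rel=0.05)
        between = means.var(ddof=1) - within * np.mean(1.0 / n_i)
        assert between == pytest.approx(0.5**2, rel=0.10)


def test_ground_truth_yaml_round_trip(tmp_path, intra_small):
    import yaml

    _, gt = intra_small
    path = tmp_path / "gt.yaml"
    gt.write(path)
    payload = yaml.safe_load(path.read_text())
    assert payload["config"]["n_years"] == 6
    assert payload["param_truth"]["br_climate"] == pytest.approx(gt.config.beta_r[1])
    assert len(payload["r_context"]) == 6
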