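"""Tests of the three-stage estimator: covariate screening, OLS recovery,
the space-time smoother against a brute-force oracle, GP limiting cases and
properties, composition coherence, and full-pipeline contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from bfequity import harmonize as hz
from bfequity import stgpr
from bfequity import synthetic as syn

from conftest import make_obs


# ---------------------------------------------------------------------------
# independent brute-force oracle for the stage-2 smoother
# ---------------------------------------------------------------------------

def stage2_oracle(target_country, target_year, residuals, geo, w):
    """Plain-loop implementation of the smoother definition.

    residuals: list of dicts with country, year, residual, national.
    """
    region = {r["country_id"]: r["region_id"] for r in geo}
    sregion = {r["country_id"]: r["super_region_id"] for r in geo}

    def tricube(dy):
        u = abs(dy) / w.time_bandwidth
        if u >= 1:
            return 0.0
        return (1 - u ** w.time_exponent) ** w.time_exponent

    num, den = 0.0, 0.0
    for j in sorted({r["country"] for r in residuals}):
        if j == target_country:
            s = 1.0
        elif region[j] == region[target_country]:
            s = w.space_weight_region
        elif sregion[j] == sregion[target_country]:
            s = w.space_weight_super_region
        else:
            continue
        nat = [(tricube(r["year"] - target_year), r["residual"])
               for r in residuals if r["country"] == j and r["national"]]
        sub = [(tricube(r["year"] - target_year), r["residual"])
               for r in residuals if r["country"] == j and not r["national"]]
        m_nat = sum(t for t, _ in nat)
        m_sub = sum(t for t, _ in sub)
        if m_nat > 0 and m_sub > 0:
            rho = (w.national_data_share * sum(t * r for t, r in nat) / m_nat
                   + (1 - w.national_data_share)
                   * sum(t * r for t, r in sub) / m_sub)
        elif m_nat > 0:
            rho = sum(t * r for t, r in nat) / m_nat
        elif m_sub > 0:
            rho = sum(t * r for t, r in sub) / m_sub
        else:
            continue
        num += s * rho
        den += s
    return num / max(1.0, den)


def run_stage2(residual_dicts, geo_df, weights, years):
    res_df = pd.DataFrame([{
        "country_id": r["country"], "year": r["year"],
        "residual": r["residual"], "national": r["national"],
        "logit_variance": 0.01,
    } for r in residual_dicts])
    grid = pd.DataFrame({
        "country_id": np.repeat(geo_df.country_id.values, len(years)),
        "year": np.tile(years, len(geo_df)),
        "pred_logit": 0.0,
    })
    fit = stgpr.Stage1Fit("x", pd.Series(dtype=float), pd.DataFrame(), None,
                          grid, res_df)
    return stgpr.fit_stage2_st(fit, geo_df, weights)


def small_geo():
    return pd.DataFrame({
        "country_id": ["A", "B", "C", "D"],
        "region_id": ["R1", "R1", "R2", "R2"],
        "super_region_id": ["S1", "S1", "S1", "S2"],
    })


class TestScreening:
    def _obs_and_covs(self, rng):
        years = np.arange(1990, 2000)
        countries = [f"C{i}" for i in range(10)]
        covs = pd.DataFrame({
            "country_id": np.repeat(countries, len(years)),
            "year": np.tile(years, len(countries)),
        })
        covs["x_indep"] = rng.normal(size=len(covs))
        covs["x_const"] = 1.7
        lv = rng.normal(-0.5, 0.6, size=len(covs))
        covs["x_copy"] = lv
        obs = make_obs([
            (f"S{i}", row.country_id, row.year, "exclusive_0_5",
             float(expit(l)), True, True)
            for i, (l, (_, row)) in enumerate(zip(lv, covs.iterrows()))
        ], sample_size=10 ** 9)
        return obs, covs

    def test_copy_covariate_has_unit_correlation(self):
        obs, covs = self._obs_and_covs(np.random.default_rng(0))
        with pytest.warns(UserWarning, match="constant"):
            rep = stgpr.screen_covariates(obs, covs)
        row = rep[(rep.covariate == "x_copy")].iloc[0]
        assert row.r == pytest.approx(1.0, abs=1e-6)
        assert row["rank"] == 1

    def test_independent_covariate_near_zero(self):
        obs, covs = self._obs_and_covs(np.random.default_rng(1))
        with pytest.warns(UserWarning):
            rep = stgpr.screen_covariates(obs, covs)
        assert abs(rep[rep.covariate == "x_indep"].r.iloc[0]) < 0.2
        assert "x_const" not in set(rep.covariate)


class TestStage1:
    def _noise_free(self, world):
        beta = {"const": -0.6, "education": 0.08, "ln_gdp": -0.15,
                "underweight": -0.9, "tfr": 0.12}
        covs = world.covariates
        lv = (beta["const"] + beta["education"] * covs.education
              + beta["ln_gdp"] * covs.ln_gdp
              + beta["underweight"] * covs.underweight
              + beta["tfr"] * covs.tfr)
        sub = covs.iloc[::4]
        obs = make_obs([
            (f"S{i}", row.country_id, row.year, "exclusive_0_5",
             float(expit(lv.iloc[idx])), True, True)
            for i, (idx, row) in enumerate(sub.iterrows())
        ], sample_size=10 ** 9)
        return beta, obs

    def test_exact_recovery_on_noise_free_data(self, world):
        beta, obs = self._noise_free(world)
        fit = stgpr.fit_stage1_ols(obs, world.covariates, "exclusive_0_5")
        for name, val in beta.items():
            assert fit.params[name] == pytest.approx(val, abs=1e-8)
        assert np.abs(fit.residuals.residual).max() < 1e-8

    def test_permutation_invariance(self, world):
        _, obs = self._noise_free(world)
        fit1 = stgpr.fit_stage1_ols(obs, world.covariates, "exclusive_0_5")
        shuffled = obs.sample(frac=1.0, random_state=5).reset_index(drop=True)
        fit2 = stgpr.fit_stage1_ols(shuffled, world.covariates, "exclusive_0_5")
        assert np.allclose(fit1.params.values, fit2.params.values, atol=1e-10)

    def test_too_few_observations_rejected(self, world):
        _, obs = self._noise_free(world)
        with pytest.raises(stgpr.PipelineError, match=">= 10"):
            stgpr.fit_stage1_ols(obs.head(5), world.covariates, "exclusive_0_5")

    def test_collinear_design_named(self, world):
        _, obs = self._noise_free(world)
        covs = world.covariates.copy()
        covs["education"] = 3.0  # constant column, collinear with intercept
        with pytest.raises(stgpr.PipelineError, match="education"):
            stgpr.fit_stage1_ols(obs, covs, "exclusive_0_5")

    def test_predicts_all_country_years(self, world):
        _, obs = self._noise_free(world)
        fit = stgpr.fit_stage1_ols(obs, world.covariates, "exclusive_0_5")
        assert len(fit.predictions) == len(world.covariates)
        assert fit.predictions.pred_logit.notna().all()


class TestStage2:
    def test_single_residual_reproduced_at_its_point(self):
        geo = small_geo()
        res = [dict(country="A", year=1995, residual=0.37, national=True)]
        out = run_stage2(res, geo, stgpr.STWeights(), np.arange(1990, 2001))
        got = out[(out.country_id == "A") & (out.year == 1995)]
        assert got.smoothed_residual.iloc[0] == pytest.approx(0.37, abs=1e-12)

    def test_national_subnational_shares(self):
        """National residuals +1 and subnational -1 at the target year with
        the default 90/10 shares combine to exactly 0.8."""
        geo = small_geo()
        res = [dict(country="A", year=1995, residual=1.0, national=True),
               dict(country="A", year=1995, residual=1.0, national=True),
               dict(country="A", year=1995, residual=-1.0, national=False)]
        out = run_stage2(res, geo, stgpr.STWeights(), np.array([1995]))
        got = out[(out.country_id == "A") & (out.year == 1995)]
        assert got.smoothed_residual.iloc[0] == pytest.approx(0.8, abs=1e-12)

    def test_sibling_country_data_attenuated_by_space_weight(self):
        geo = small_geo()
        w = stgpr.STWeights()
        res = [dict(country="B", year=1995, residual=0.6, national=True)]
        out = run_stage2(res, geo, w, np.array([1995]))
        at_a = out[(out.country_id == "A") & (out.year == 1995)]
        assert at_a.smoothed_residual.iloc[0] == pytest.approx(
            w.space_weight_region * 0.6, abs=1e-12)
        at_c = out[(out.country_id == "C") & (out.year == 1995)]
        assert at_c.smoothed_residual.iloc[0] == pytest.approx(
            w.space_weight_super_region * 0.6, abs=1e-12)
        at_d = out[(out.country_id == "D") & (out.year == 1995)]
        assert at_d.smoothed_residual.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        geo = small_geo()
        geo_recs = geo.to_dict("records")
        years = np.arange(1990, 2001)
        for _ in range(30):
            n = rng.integers(1, 11)
            res = [dict(country=rng.choice(geo.country_id),
                        year=int(rng.integers(1990, 2001)),
                        residual=float(rng.normal()),
                        national=bool(rng.random() < 0.7))
                   for _ in range(n)]
            w = stgpr.STWeights(
                time_bandwidth=float(rng.uniform(3, 15)),
                space_weight_region=float(rng.uniform(0.2, 0.8)),
                space_weight_super_region=float(rng.uniform(0.05, 0.5)),
                national_data_share=float(rng.uniform(0.6, 1.0)))
            out = run_stage2(res, geo, w, years).set_index(
                ["country_id", "year"])
            for c in geo.country_id:
                for t in years:
                    expected = stage2_oracle(c, t, res, geo_recs, w)
                    assert out.loc[(c, t), "smoothed_residual"] == pytest.approx(
                        expected, abs=1e-12)

    def test_empty_residuals_warns_and_returns_zero(self):
        geo = small_geo()
        with pytest.warns(UserWarning, match="no residuals"):
            out = run_stage2([], geo, stgpr.STWeights(), np.arange(1990, 1995))
        assert (out.smoothed_residual == 0).all()


def flat_prior(countries, years, level=0.4):
    return pd.DataFrame({
        "country_id": np.repeat(countries, len(years)),
        "year": np.tile(years, len(countries)),
        "prior_logit": float(logit(level)),
    })


class TestStage3:
    years = np.arange(1990, 2011)

    def test_no_data_posterior_equals_prior(self):
        prior = flat_prior(["A"], self.years)
        obs = make_obs([]).assign(variance_inflation=[])
        cfg = stgpr.GPRConfig(amplitude=1e-8, n_draws=200, jitter=1e-14)
        d = stgpr.fit_stage3_gpr(prior, obs, cfg, seed=1)
        assert np.abs(logit(d.draws).mean(axis=2) - logit(0.4)).max() < 1e-6
        assert np.allclose(d.draws, 0.4, atol=1e-4)

    def test_no_data_interval_reflects_kernel_amplitude(self):
        prior = flat_prior(["A"], self.years)
        obs = make_obs([]).assign(variance_inflation=[])
        cfg = stgpr.GPRConfig(amplitude=0.3, n_draws=2000)
        d = stgpr.fit_stage3_gpr(prior, obs, cfg, seed=1)
        lv = logit(d.draws)
        assert abs(lv.mean() - logit(0.4)) < 0.05
        assert np.allclose(lv.std(axis=2), 0.3, atol=0.05)

    def test_zero_variance_observation_interpolated(self):
        prior = flat_prior(["A"], self.years)
        obs = make_obs([("S0", "A", 2000, "x", 0.7, True, True)],
                       sample_size=10 ** 9)
        obs["variance"] = 0.0
        cfg = stgpr.GPRConfig(amplitude=0.3, nsv=0.0, jitter=1e-12, n_draws=200)
        d = stgpr.fit_stage3_gpr(prior, obs, cfg, seed=2)
        yi = int(np.where(d.years == 2000)[0][0])
        assert abs(logit(d.draws[0, yi, :]).mean() - logit(0.7)) < 1e-6
        assert np.abs(logit(d.draws[0, yi, :]) - logit(0.7)).max() < 1e-4

    def test_posterior_variance_shrinks_with_more_data(self):
        prior = flat_prior(["A"], self.years)
        cfg = stgpr.GPRConfig(amplitude=0.3, nsv=0.01, n_draws=4000)
        obs1 = make_obs([("S0", "A", 2000, "x", 0.6, True, True)])
        obs2 = make_obs([("S0", "A", 2000, "x", 0.6, True, True),
                         ("S1", "A", 2000, "x", 0.62, True, True)])
        d1 = stgpr.fit_stage3_gpr(prior, obs1, cfg, seed=3)
        d2 = stgpr.fit_stage3_gpr(prior, obs2, cfg, seed=3)
        yi = int(np.where(d1.years == 2000)[0][0])
        v1 = logit(d1.draws[0, yi]).var()
        v2 = logit(d2.draws[0, yi]).var()
        assert v2 <= v1 * 1.05

    def test_moving_observation_up_never_lowers_posterior_mean(self):
        prior = flat_prior(["A"], self.years)
        cfg = stgpr.GPRConfig(amplitude=0.3, nsv=0.01, n_draws=4000)
        base = [("S0", "A", 1995, "x", 0.5, True, True),
                ("S1", "A", 2000, "x", 0.55, True, True),
                ("S2", "A", 2005, "x", 0.5, True, True)]
        obs_lo = make_obs(base)
        base_hi = [base[0], ("S1", "A", 2000, "x", 0.70, True, True), base[2]]
        obs_hi = make_obs(base_hi)
        d_lo = stgpr.fit_stage3_gpr(prior, obs_lo, cfg, seed=4)
        d_hi = stgpr.fit_stage3_gpr(prior, obs_hi, cfg, seed=4)
        yi = int(np.where(d_lo.years == 2000)[0][0])
        m_lo = logit(d_lo.draws[0, yi]).mean()
        m_hi = logit(d_hi.draws[0, yi]).mean()
        assert m_hi >= m_lo - 0.01

    def test_draws_within_unit_interval_and_ordered_quantiles(self, world,
                                                              harmonized):
        res = stgpr.run_pipeline(harmonized, world.covariates, world.countries,
                                 seed=7)
        for d in res.indicators.values():
            assert (d.draws >= 0).all() and (d.draws <= 1).all()
            assert (d.lower_95 <= d.mean + 1e-12).all()
            assert (d.mean <= d.upper_95 + 1e-12).all()


class TestComposition:
    def test_cumulative_differencing_example(self):
        out = stgpr.enforce_composition(np.array([0.3]), np.array([0.5]),
                                        np.array([0.9]))
        assert out["exclusive_0_5"][0] == pytest.approx(0.30)
        assert out["predominant_0_5"][0] == pytest.approx(0.20)
        assert out["partial_0_5"][0] == pytest.approx(0.40)
        assert out["none_0_5"][0] == pytest.approx(0.10)

    def test_shares_nonnegative_and_conserved_for_any_draws(self):
        rng = np.random.default_rng(11)
        a, b, c = rng.uniform(0, 1, (3, 5, 7, 100))
        out = stgpr.enforce_composition(a, b, c)
        total = sum(out.values())
        assert np.allclose(total, 1.0, atol=1e-12)
        for v in out.values():
            assert (v >= -1e-15).all()


class TestPipeline:
    def test_complete_grid(self, world, harmonized):
        res = stgpr.run_pipeline(harmonized, world.covariates, world.countries,
                                 seed=7)
        est = res.estimates()
        assert len(est) == 24 * 21 * 6
        assert est["mean"].notna().all()
        assert set(est.indicator) == set(syn.INDICATORS)

    def test_same_seed_identical_draws(self, world, harmonized):
        r1 = stgpr.run_pipeline(harmonized, world.covariates, world.countries,
                                seed=9)
        r2 = stgpr.run_pipeline(harmonized, world.covariates, world.countries,
                                seed=9)
        for ind in r1.indicators:
            assert np.array_equal(r1.indicators[ind].draws,
                                  r2.indicators[ind].draws)

    def test_smoothing_improves_on_stage1_alone(self):
        """Full-pipeline RMSE beats the stage-1-only surface in most worlds."""
        wins = 0
        n = 10
        for seed in range(n):
            cfg = syn.desk_config(seed=300 + seed)
            w = syn.generate_world(cfg)
            s = syn.simulate_surveys(w)
            corr, _ = hz.apply_corrections(s, hz.estimate_correction_factors(s))
            res = stgpr.run_pipeline(corr, w.covariates, w.countries,
                                     seed=seed)
            truth = w.trajectories.rename(columns={"true_prevalence": "truth"})
            full = res.estimates().merge(truth,
                                         on=["country_id", "year", "indicator"])
            rmse_full = np.sqrt(((full["mean"] - full.truth) ** 2).mean())
            s1 = res.stage1_only_estimates()
            s1 = s1[s1.indicator == "cum_exclusive"].rename(
                columns={"indicator": "drop"})
            excl_truth = truth[truth.indicator == "exclusive_0_5"]
            s1 = s1.merge(excl_truth, on=["country_id", "year"])
            rmse_s1 = np.sqrt(((s1["mean"] - s1.truth) ** 2).mean())
            full_excl = full[full.indicator == "exclusive_0_5"]
            rmse_full_excl = np.sqrt(
                ((full_excl["mean"] - full_excl.truth) ** 2).mean())
            wins += rmse_full_excl < rmse_s1
        assert wins > n / 2

    def test_matern_kernel_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.gaussian_process.kernels")
        x = np.linspace(0, 20, 15)
        ours = stgpr.matern52(x, x, amplitude=0.7, length_scale=8.0)
        theirs = 0.49 * sk.Matern(length_scale=8.0, nu=2.5)(x[:, None])
        assert np.allclose(ours, theirs, atol=1e-12)
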