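"""Replicate studies against generator truth: interval calibration,
coefficient recovery, crosswalk recovery, wealth-model recovery and trend
classification rates.

These functions regenerate synthetic worlds with known ground truth, run the
corresponding estimator, and measure how well truth is recovered. They back
both the test suite and the reproduction script, and every reported number
is computed at call time.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import spearmanr

from . import harmonize as hz
from . import stgpr
from . import synthetic as syn
from . import wealth as wl

STAGE1_TRUE_COEFFICIENTS = {
    "education": 0.10, "ln_gdp": -0.20, "underweight": -1.0, "tfr": 0.10,
}


def _replicate_world(seed: int):
    cfg = syn.desk_config(seed=seed)
    world = syn.generate_world(cfg)
    surveys = syn.simulate_surveys(world)
    return world, surveys


def calibration_study(n_replicates: int = 100, seed: int = 0,
                      near_years: int = 3) -> dict:
    """Coverage of the 95% intervals and MAE of the posterior mean, over
    country-years within ``near_years`` of an observation, pooled across
    replicate desk-scale worlds and all six indicators."""
    covered = total = 0
    abs_err = []
    for i in range(n_replicates):
        world, surveys = _replicate_world(seed + i)
        harmonized, _ = hz.apply_corrections(
            surveys, hz.estimate_correction_factors(surveys))
        res = stgpr.run_pipeline(harmonized, world.covariates,
                                 world.countries, seed=seed + i)
        est = res.estimates()
        truth = world.trajectories.rename(
            columns={"true_prevalence": "truth"})
        m = est.merge(truth, on=["country_id", "year", "indicator"])
        obs_years = surveys.groupby("country_id")["year"].unique()
        near = m.apply(
            lambda r: np.min(np.abs(np.asarray(
                obs_years.get(r.country_id, [10 ** 6])) - r.year))
            <= near_years, axis=1)
        mm = m[near]
        covered += int(((mm.truth >= mm.lower_95)
                        & (mm.truth <= mm.upper_95)).sum())
        total += len(mm)
        abs_err.append((mm["mean"] - mm.truth).abs().mean())
    return {"coverage": covered / total, "mae_pp": 100 * float(np.mean(abs_err)),
            "n_cells": total, "n_replicates": n_replicates}


def stage1_coverage_study(n_replicates: int = 100, seed: int = 0,
                          stream: str = "cum_exclusive") -> dict:
    """Per-coefficient count of replicates whose 95% interval covers the
    generating value, for the stage-1 fit on standard national observations."""
    hits = {k: 0 for k in STAGE1_TRUE_COEFFICIENTS}
    for i in range(n_replicates):
        world, surveys = _replicate_world(seed + i)
        s = surveys[surveys.standard_definition].assign(variance_inflation=0.0)
        sobs = stgpr.build_stream_observations(s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = stgpr.fit_stage1_ols(sobs, world.covariates, stream,
                                       geo=world.countries)
        for name, true_val in STAGE1_TRUE_COEFFICIENTS.items():
            lo, hi = fit.conf_int.loc[name]
            hits[name] += int(lo <= true_val <= hi)
    return {"hits": hits, "n_replicates": n_replicates,
            "min_coverage": min(hits.values()) / n_replicates}


def crosswalk_recovery_study(n_replicates: int = 100, seed: int = 0,
                             indicator: str = "exclusive_0_5") -> dict:
    """Mean estimated crosswalk shift across replicate worlds whose generator
    distorts non-standard reports by -0.4 logits (true shift +0.4)."""
    shifts = []
    for i in range(n_replicates):
        _, surveys = _replicate_world(seed + i)
        m = hz.estimate_correction_factors(surveys)[indicator]
        if m.usable:
            shifts.append(m.additive_logit_shift)
    shifts = np.asarray(shifts)
    return {"mean_shift": float(shifts.mean()),
            "mc_se": float(shifts.std(ddof=1) / np.sqrt(len(shifts))),
            "true_shift": 0.4, "n_replicates": len(shifts)}


def wealth_recovery_study(n_replicates: int = 20, seed: int = 0,
                          n_households: int = 2000, n_assets: int = 12) -> dict:
    """Spearman correlation of estimated vs true income and quintile
    agreement, averaged over replicate household worlds."""
    rho, exact, adjacent = [], [], []
    for i in range(n_replicates):
        hh = syn.simulate_households(n_households, n_assets, seed=seed + i)
        assets = hh[[c for c in hh.columns if c.startswith("asset_")]]
        sel = wl.select_assets(assets)
        model = wl.fit_asset_cutpoints(sel.table)
        inc = wl.estimate_permanent_income(sel.table, model, hh.household_id)
        rho.append(spearmanr(inc.permanent_income, hh.true_income).statistic)
        diff = np.abs(inc.quintile.values - hh.true_quintile.values)
        exact.append((diff == 0).mean())
        adjacent.append((diff <= 1).mean())
    return {"spearman": float(np.mean(rho)),
            "exact_agreement": float(np.mean(exact)),
            "adjacent_agreement": float(np.mean(adjacent)),
            "n_replicates": n_replicates}


def trend_classifier_study(n_replicates: int = 100, seed: int = 0) -> dict:
    """Verdict rates: 'uniform' on null-gradient worlds and
    'top-concentrated' on worlds whose increase is confined to the top two
    quintiles."""
    uniform = top = 0
    for i in range(n_replicates):
        null = syn.simulate_quintile_series(seed=seed + i, country_id="null")
        v = wl.quintile_trend_comparison(null)[0]
        uniform += v.verdict == "uniform"
        conc = syn.simulate_quintile_series(
            seed=seed + i, country_id="top",
            slopes=np.array([0, 0, 0, 0.015, 0.015]))
        v2 = wl.quintile_trend_comparison(conc)[0]
        top += v2.verdict == "top-concentrated"
    return {"uniform_rate": uniform / n_replicates,
            "top_rate": top / n_replicates, "n_replicates": n_replicates}
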