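"""Synthetic ground-truth world: geography, trajectories, covariates, surveys,
households and burden envelopes.

The generator emulates the data environment of a multi-country breastfeeding
prevalence study: a nested geographic hierarchy (super-region > region >
country), smooth logit-linear prevalence trajectories for six indicators with
spatially correlated random effects, country-year covariates with known
loadings on the prevalence logits, noisy survey observations (binomial
sampling, subnational bias, non-standard-definition distortion), household
asset tables generated from a probit measurement model on a latent permanent
income, and cause-specific burden envelopes for diarrhea and pneumonia.

Everything is deterministic given (config, seed): all randomness flows from
one root seed through named substreams (see :mod:`bfequity._rng`), so each
component can be regenerated independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from ._rng import substream

#: The six reported breastfeeding indicators.
INDICATORS = (
    "initiation_24h",
    "exclusive_0_5",
    "predominant_0_5",
    "partial_0_5",
    "continued_6_11",
    "continued_12_23",
)

#: The six modelled streams. The three 0-5-month category indicators are
#: generated (and later modelled) through nested cumulative quantities:
#: exclusive ⊆ exclusive∪predominant ⊆ any breastfeeding.
STREAMS = (
    "cum_exclusive",
    "cum_excl_pred",
    "cum_any_bf",
    "initiation_24h",
    "continued_6_11",
    "continued_12_23",
)

CUMULATIVE_STREAMS = STREAMS[:3]

COVARIATES = ("education", "ln_gdp", "underweight", "tfr")

#: Years of life lost per under-five death used to split DALYs into a
#: mortality (YLL) and morbidity (YLD) component. Standard life table value
#: for a death in early childhood, undiscounted.
YLL_PER_DEATH = 86.0


def _default_loadings() -> dict:
    """True covariate loadings on each stream's logit (per covariate unit)."""
    base = {"education": 0.10, "ln_gdp": -0.20, "underweight": -1.0, "tfr": 0.10}
    return {s: dict(base) for s in STREAMS}


#: Typical logit levels for each stream, before covariate contributions.
_STREAM_TARGET_LOGIT = {
    "cum_exclusive": -0.85,   # exclusive ~ 0.30
    "cum_excl_pred": -0.20,   # exclusive+predominant ~ 0.45
    "cum_any_bf": 1.50,       # any breastfeeding ~ 0.82
    "initiation_24h": -0.50,
    "continued_6_11": 1.30,
    "continued_12_23": 0.30,
}

# Covariate generation: (super-region mean low, high), country sd, slope mean, slope sd
_COV_GEN = {
    "education": dict(sr_lo=3.0, sr_hi=9.0, region_sd=0.7, country_sd=0.5,
                      slope_mean=0.08, slope_sd=0.03),
    "ln_gdp": dict(sr_lo=6.5, sr_hi=8.5, region_sd=0.5, country_sd=0.4,
                   slope_mean=0.02, slope_sd=0.01),
    "underweight": dict(sr_lo=0.10, sr_hi=0.35, region_sd=0.04, country_sd=0.03,
                        slope_mean=-0.003, slope_sd=0.002),
    "tfr": dict(sr_lo=3.0, sr_hi=6.0, region_sd=0.6, country_sd=0.4,
                slope_mean=-0.05, slope_sd=0.02),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic world.

    Defaults define the desk-scale study conditions: a 3 x 2 x 4 = 24-country
    world observed 1990-2010, about five surveys per country of 3,000
    children each, 15% subnational surveys biased by +0.3 on the logit scale
    and 20% non-standard-definition surveys distorted by -0.4.
    """

    n_super_regions: int = 3
    n_regions_per: int = 2
    n_countries_per: int = 4
    year_start: int = 1990
    year_end: int = 2010
    surveys_per_country: float = 5.0
    survey_sample_size: int = 3000
    subnational_fraction: float = 0.15
    nonstandard_fraction: float = 0.20
    dual_report_fraction: float = 0.5
    subnational_bias_logit: float = 0.3
    nonstandard_distortion_logit: float = -0.4
    loadings: dict = field(default_factory=_default_loadings)
    re_sd_super: float = 0.20
    re_sd_region: float = 0.25
    re_sd_country: float = 0.30
    re_slope_sd: float = 0.015
    stream_re_sd: float = 0.10
    stream_slope_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("subnational_fraction", "nonstandard_fraction",
                     "dual_report_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.survey_sample_size < 1:
            raise ValueError("survey_sample_size must be >= 1")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        if min(self.n_super_regions, self.n_regions_per, self.n_countries_per) < 1:
            raise ValueError("hierarchy counts must be >= 1")
        if self.surveys_per_country < 0:
            raise ValueError("surveys_per_country must be >= 0")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def n_countries(self) -> int:
        return self.n_super_regions * self.n_regions_per * self.n_countries_per


def desk_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Desk-scale preset (24 countries) used throughout the test suite."""
    return replace(SyntheticConfig(seed=seed), **overrides)


def paper_scale_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A 137-country world mirroring the scale of the real analysis grid
    (7 super-regions x ~20 countries); not used by the default test run."""
    cfg = SyntheticConfig(
        n_super_regions=7, n_regions_per=3, n_countries_per=7, seed=seed
    )
    return replace(cfg, **overrides)


@dataclass
class World:
    """Ground-truth world returned by :func:`generate_world`."""

    config: SyntheticConfig
    countries: pd.DataFrame      # country_id, region_id, super_region_id, population
    stream_logits: pd.DataFrame  # country_id, year, <stream columns> (truth, logit scale)
    trajectories: pd.DataFrame   # country_id, year, indicator, true_prevalence
    covariates: pd.DataFrame     # country_id, year, education, ln_gdp, underweight, tfr

    @property
    def years(self) -> np.ndarray:
        return self.config.years

    def true_prevalence(self, country_id: str, year: int, indicator: str) -> float:
        t = self.trajectories
        row = t[(t.country_id == country_id) & (t.year == year)
                & (t.indicator == indicator)]
        return float(row.true_prevalence.iloc[0])


def _make_hierarchy(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for s in range(config.n_super_regions):
        sr = f"SR{s:02d}"
        for r in range(config.n_regions_per):
            rid = f"{sr}_R{r:02d}"
            for c in range(config.n_countries_per):
                rows.append({
                    "country_id": f"{rid}_C{c:02d}",
                    "region_id": rid,
                    "super_region_id": sr,
                })
    df = pd.DataFrame(rows)
    # annual births; lognormal gives a realistic spread of country sizes
    df["population"] = np.round(rng.lognormal(mean=11.0, sigma=0.8, size=len(df)))
    return df


def _make_covariates(config: SyntheticConfig, countries: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    years = config.years
    tc = years - years.mean()
    n = len(countries)
    srs = countries.super_region_id.unique()
    regs = countries.region_id.unique()
    out = {"country_id": np.repeat(countries.country_id.values, len(years)),
           "year": np.tile(years, n)}
    for cov, g in _COV_GEN.items():
        sr_base = dict(zip(srs, rng.uniform(g["sr_lo"], g["sr_hi"], len(srs))))
        r_off = dict(zip(regs, rng.normal(0.0, g["region_sd"], len(regs))))
        base = (countries.super_region_id.map(sr_base).values
                + countries.region_id.map(r_off).values
                + rng.normal(0.0, g["country_sd"], n))
        slope = rng.normal(g["slope_mean"], g["slope_sd"], n)
        vals = base[:, None] + slope[:, None] * tc[None, :]
        if cov == "underweight":
            vals = np.clip(vals, 0.01, 0.60)
        if cov == "tfr":
            vals = np.clip(vals, 1.0, None)
        out[cov] = vals.ravel()
    return pd.DataFrame(out)


def generate_world(config: SyntheticConfig) -> World:
    """Generate the full ground-truth world for the given configuration.

    Stream logits are linear in time: covariate loadings (covariates are
    themselves linear in time per country) plus nested intercept random
    effects (super-region, region, country — shared across streams so that
    the cumulative ordering is stable) plus small stream-specific offsets
    and slopes. Cumulative ordering exclusive <= excl∪pred <= any is enforced
    with a minimum logit gap of 0.05 (rarely binding under the defaults).
    """
    geo_rng = substream(config.seed, "world", "geo")
    cov_rng = substream(config.seed, "world", "covariates")
    eff_rng = substream(config.seed, "world", "effects")

    countries = _make_hierarchy(config, geo_rng)
    covariates = _make_covariates(config, countries, cov_rng)

    n = len(countries)
    years = config.years
    tc = years - years.mean()

    srs = countries.super_region_id.unique()
    regs = countries.region_id.unique()
    u_sr = dict(zip(srs, eff_rng.normal(0.0, config.re_sd_super, len(srs))))
    u_r = dict(zip(regs, eff_rng.normal(0.0, config.re_sd_region, len(regs))))
    u_c = eff_rng.normal(0.0, config.re_sd_country, n)
    b_c = eff_rng.normal(0.0, config.re_slope_sd, n)
    shared = (countries.super_region_id.map(u_sr).values
              + countries.region_id.map(u_r).values + u_c)

    cov_wide = covariates.set_index(["country_id", "year"])
    z = {}
    for s in STREAMS:
        loads = config.loadings.get(s, {})
        lin = np.zeros((n, len(years)))
        centered_means = {}
        for cov in COVARIATES:
            beta = loads.get(cov, 0.0)
            vals = cov_wide[cov].values.reshape(n, len(years))
            lin += beta * vals
            centered_means[cov] = vals.mean()
        intercept = _STREAM_TARGET_LOGIT[s] - sum(
            loads.get(cov, 0.0) * centered_means[cov] for cov in COVARIATES
        )
        s_off = eff_rng.normal(0.0, config.stream_re_sd, n)
        s_slope = eff_rng.normal(0.0, config.stream_slope_sd, n)
        z[s] = (intercept + lin
                + (shared + s_off)[:, None]
                + (b_c + s_slope)[:, None] * tc[None, :])

    # enforce the nested cumulative ordering with a minimum logit gap
    gap = 0.05
    z["cum_excl_pred"] = np.maximum(z["cum_excl_pred"], z["cum_exclusive"] + gap)
    z["cum_any_bf"] = np.maximum(z["cum_any_bf"], z["cum_excl_pred"] + gap)

    stream_logits = pd.DataFrame({
        "country_id": np.repeat(countries.country_id.values, len(years)),
        "year": np.tile(years, n),
        **{s: z[s].ravel() for s in STREAMS},
    })

    p1 = expit(z["cum_exclusive"])
    p2 = expit(z["cum_excl_pred"])
    p3 = expit(z["cum_any_bf"])
    prev = {
        "exclusive_0_5": p1,
        "predominant_0_5": p2 - p1,
        "partial_0_5": p3 - p2,
        "initiation_24h": expit(z["initiation_24h"]),
        "continued_6_11": expit(z["continued_6_11"]),
        "continued_12_23": expit(z["continued_12_23"]),
    }
    frames = []
    for ind in INDICATORS:
        frames.append(pd.DataFrame({
            "country_id": np.repeat(countries.country_id.values, len(years)),
            "year": np.tile(years, n),
            "indicator": ind,
            "true_prevalence": prev[ind].ravel(),
        }))
    trajectories = pd.concat(frames, ignore_index=True)

    return World(config=config, countries=countries, stream_logits=stream_logits,
                 trajectories=trajectories, covariates=covariates)


# ---------------------------------------------------------------------------
# surveys
# ---------------------------------------------------------------------------

def simulate_surveys(world: World, config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Simulate survey observations of all six indicators.

    Per country the number of surveys is Poisson(surveys_per_country), years
    uniform over the study period. Each survey draws a multinomial sample of
    ``survey_sample_size`` children over the 0-5-month feeding categories
    (so the three category estimates are internally coherent) and independent
    binomial samples for initiation and the two continued indicators.

    Subnational surveys measure a population whose stream logits are shifted
    by ``subnational_bias_logit``. Non-standard surveys report
    ``expit(logit(p) + nonstandard_distortion_logit)`` for every indicator;
    a ``dual_report_fraction`` of them also contribute a standard-definition
    re-analysis based on an independent sample of the same population, which
    is what makes the harmonization crosswalk estimable.

    Returns a long table with one row per (survey, indicator): survey_id,
    country_id, year, indicator, value, sample_size, variance, national,
    standard_definition.
    """
    if config is None:
        config = world.config
    rng = substream(config.seed, "surveys")
    zwide = world.stream_logits.set_index(["country_id", "year"])
    n_size = config.survey_sample_size
    rows = []
    sid = 0
    for country in world.countries.country_id:
        k = rng.poisson(config.surveys_per_country)
        survey_years = rng.integers(config.year_start, config.year_end + 1, size=k)
        for year in survey_years:
            zrow = zwide.loc[(country, int(year))]
            national = rng.random() >= config.subnational_fraction
            nonstandard = rng.random() < config.nonstandard_fraction
            dual = nonstandard and (rng.random() < config.dual_report_fraction)
            bias = 0.0 if national else config.subnational_bias_logit
            zs = {s: zrow[s] + bias for s in STREAMS}

            def draw_values(r: np.random.Generator) -> dict:
                c1, c2, c3 = (expit(zs[s]) for s in CUMULATIVE_STREAMS)
                probs = np.array([c1, c2 - c1, c3 - c2, 1.0 - c3])
                counts = r.multinomial(n_size, probs)
                vals = {
                    "exclusive_0_5": counts[0] / n_size,
                    "predominant_0_5": counts[1] / n_size,
                    "partial_0_5": counts[2] / n_size,
                }
                for s in ("initiation_24h", "continued_6_11", "continued_12_23"):
                    vals[s] = r.binomial(n_size, expit(zs[s])) / n_size
                return vals

            emitted = [(draw_values(rng), not nonstandard)]
            if dual:
                # independent re-analysis of the same population under the
                # standard definition (DHS-microdata style)
                emitted.append((draw_values(rng), True))

            for vals, standard in emitted:
                survey_id = f"S{sid:05d}"
                for ind in INDICATORS:
                    v = vals[ind]
                    if not standard:
                        v_cl = np.clip(v, 1.0 / (4 * n_size), 1 - 1.0 / (4 * n_size))
                        v = float(expit(logit(v_cl) + config.nonstandard_distortion_logit))
                    rows.append({
                        "survey_id": survey_id,
                        "country_id": country,
                        "year": int(year),
                        "indicator": ind,
                        "value": v,
                        "sample_size": n_size,
                        "variance": v * (1 - v) / n_size,
                        "national": national,
                        "standard_definition": standard,
                    })
                sid += 1
    return pd.DataFrame(rows, columns=[
        "survey_id", "country_id", "year", "indicator", "value", "sample_size",
        "variance", "national", "standard_definition",
    ])


# ---------------------------------------------------------------------------
# households
# ---------------------------------------------------------------------------

def simulate_households(
    n_households: int = 2000,
    n_assets: int = 12,
    seed: int = 0,
    discriminations: np.ndarray | None = None,
    cutpoints: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate a household asset table from a probit measurement model.

    Latent permanent income y ~ N(0,1) per household; asset k is owned with
    probability Phi(d_k (y - c_k)). Defaults: discriminations d ~ U(0.5, 1.5),
    cutpoints spread evenly over [-2, 2] so ownership rates span roughly
    (0.05, 0.95). Columns: household_id, asset_00.., true_income,
    true_quintile. The generating d and c are stored in ``df.attrs``.

    Assets that come out constant in the simulated sample (e.g. a cutpoint of
    -inf / never-owned asset) are dropped with a warning: they carry no
    information about income.
    """
    if n_assets < 3:
        raise ValueError("n_assets must be >= 3 (income not identifiable)")
    rng = substream(seed, "households")
    if discriminations is None:
        discriminations = rng.uniform(0.5, 1.5, n_assets)
    else:
        discriminations = np.asarray(discriminations, dtype=float)
    if cutpoints is None:
        cutpoints = np.linspace(-2.0, 2.0, n_assets)
    else:
        cutpoints = np.asarray(cutpoints, dtype=float)
    if len(discriminations) != n_assets or len(cutpoints) != n_assets:
        raise ValueError("discriminations/cutpoints length must equal n_assets")

    y = rng.normal(0.0, 1.0, n_households)
    with np.errstate(invalid="ignore"):
        p_own = norm.cdf(discriminations[None, :] * (y[:, None] - cutpoints[None, :]))
    p_own = np.nan_to_num(p_own, nan=0.0)  # d*(y - (-inf)) conventions
    owned = (rng.random((n_households, n_assets)) < p_own).astype(int)

    cols = {f"asset_{k:02d}": owned[:, k] for k in range(n_assets)}
    df = pd.DataFrame({"household_id": [f"H{h:05d}" for h in range(n_households)],
                       **cols})
    constant = [c for c in cols if df[c].nunique() == 1]
    if constant:
        warnings.warn(
            f"dropping {len(constant)} constant asset column(s): {constant}",
            UserWarning, stacklevel=2,
        )
        df = df.drop(columns=constant)
    df["true_income"] = y
    order = np.argsort(y, kind="stable")
    quint = np.empty(n_households, dtype=int)
    splits = np.array_split(order, 5)
    for q, idx in enumerate(splits, start=1):
        quint[idx] = q
    df["true_quintile"] = quint
    df.attrs["discriminations"] = discriminations
    df.attrs["cutpoints"] = cutpoints
    return df


def simulate_child_records(
    households: pd.DataFrame,
    base_prevalence: float = 0.35,
    quintile_gradient: float = 0.0,
    children_per_household: int = 1,
    seed: int = 0,
    quintile_col: str = "true_quintile",
) -> pd.DataFrame:
    """Child-level breastfeeding records linked to households.

    Prevalence in quintile q is base + gradient*(q - 3), clipped to (0, 1).
    """
    rng = substream(seed, "children")
    hh = households[["household_id", quintile_col]].loc[
        households.index.repeat(children_per_household)
    ]
    p = np.clip(base_prevalence + quintile_gradient * (hh[quintile_col].values - 3),
                1e-6, 1 - 1e-6)
    return pd.DataFrame({
        "household_id": hh.household_id.values,
        "breastfed": (rng.random(len(hh)) < p).astype(int),
    })


def simulate_quintile_series(
    n_surveys: int = 5,
    year_start: int = 1995,
    year_end: int = 2010,
    base_prevalence: float = 0.35,
    slopes: np.ndarray | None = None,
    n_children_per_quintile: int = 400,
    seed: int = 0,
    country_id: str = "C00",
) -> pd.DataFrame:
    """Per-quintile prevalence series over repeated surveys of one country.

    ``slopes`` gives the true per-quintile trend in proportion per year
    (length 5; default all zero, the null-gradient world). Observations are
    binomial draws of ``n_children_per_quintile`` children per quintile.
    """
    if slopes is None:
        slopes = np.zeros(5)
    slopes = np.asarray(slopes, dtype=float)
    if slopes.shape != (5,):
        raise ValueError("slopes must have length 5")
    rng = substream(seed, "quintile_series", country_id)
    years = np.linspace(year_start, year_end, n_surveys)
    t0 = (year_start + year_end) / 2.0
    rows = []
    n = n_children_per_quintile
    for year in years:
        for q in range(1, 6):
            p = float(np.clip(base_prevalence + slopes[q - 1] * (year - t0),
                              1e-4, 1 - 1e-4))
            obs = rng.binomial(n, p) / n
            se = np.sqrt(max(obs * (1 - obs), 1e-8) / n)
            rows.append({"country_id": country_id, "year": year, "quintile": q,
                         "prevalence": obs, "se": se, "n_children": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# burden envelopes
# ---------------------------------------------------------------------------

_CAUSES = ("diarrhea", "pneumonia")
_AGE_GROUPS = ("0_5m", "6_23m")

# baseline deaths per birth by (cause, age group)
_BASE_DEATH_RATE = {
    ("diarrhea", "0_5m"): 0.004,
    ("diarrhea", "6_23m"): 0.003,
    ("pneumonia", "0_5m"): 0.005,
    ("pneumonia", "6_23m"): 0.004,
}


def simulate_burden_background(world: World) -> pd.DataFrame:
    """Cause-specific deaths and DALYs by country-year, cause and age group.

    Deaths = population x a country-specific rate declining ~2%/year; DALYs =
    deaths x YLL_PER_DEATH x (1 + morbidity share), so DALYs >= deaths x
    YLL_PER_DEATH always. Rates are drawn independently of population, so the
    whole table is exactly linear in population.
    """
    rng = substream(world.config.seed, "burden_background")
    years = world.config.years
    tc = years - years[0]
    rows = []
    for _, crow in world.countries.iterrows():
        pop = float(crow.population)
        for cause in _CAUSES:
            for age in _AGE_GROUPS:
                base = _BASE_DEATH_RATE[(cause, age)] * rng.lognormal(0.0, 0.4)
                decline = rng.uniform(0.01, 0.03)
                yld_share = rng.uniform(0.02, 0.08)
                rate = base * np.exp(-decline * tc)
                deaths = pop * rate
                dalys = deaths * YLL_PER_DEATH * (1.0 + yld_share)
                for y, d, dl in zip(years, deaths, dalys):
                    rows.append({"country_id": crow.country_id, "year": int(y),
                                 "cause": cause, "age_group": age,
                                 "deaths": d, "dalys": dl})
    return pd.DataFrame(rows)


def simulate_comparison_risks(world: World, background: pd.DataFrame) -> pd.DataFrame:
    """Synthetic attributable-DALY envelopes for comparator child risk factors
    (used only to exercise the ranking logic; real analyses supply these)."""
    rng = substream(world.config.seed, "comparison_risks")
    total = (background.groupby(["country_id", "year"], as_index=False)
             .dalys.sum().rename(columns={"dalys": "total_dalys"}))
    frames = []
    for risk, lo, hi in (("underweight", 0.05, 0.5), ("water_sanitation", 0.02, 0.3)):
        share = rng.uniform(lo, hi, size=len(world.countries))
        share_map = dict(zip(world.countries.country_id, share))
        f = total.copy()
        f["risk"] = risk
        f["attributable_dalys"] = f.total_dalys * f.country_id.map(share_map)
        frames.append(f[["country_id", "year", "risk", "attributable_dalys"]])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# convenience: cutpoint helper used by examples/tests
# ---------------------------------------------------------------------------

def theoretical_ownership_rate(cutpoint: float, discrimination: float) -> float:
    """Population ownership rate implied by (cutpoint, discrimination) under
    a standard-normal income: Phi(-d c / sqrt(1 + d^2))."""
    d, c = discrimination, cutpoint
    return float(norm.cdf(-d * c / np.sqrt(1.0 + d * d)))
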