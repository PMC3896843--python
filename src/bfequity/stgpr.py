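"""Three-stage prevalence estimation: covariate OLS, locally weighted
spatio-temporal residual smoothing, and Gaussian-process regression.

All modelling happens on the logit scale. Stage 1 regresses the logit of
observed prevalence on four country-year covariates (female education, log
GDP per capita, child underweight, total fertility rate) and predicts a
first-pass surface for every country-year. Stage 2 smooths the stage-1
residuals over space (the region hierarchy) and time and adds them back,
down-weighting non-nationally-representative data so their combined
contribution is 10% wherever national data are also present. Stage 3 treats
the stage-1+2 surface as the prior mean of a per-country Gaussian process
over years (Matérn 5/2 kernel) with heteroscedastic observation noise, and
samples 1,000 posterior draws; means and 95% intervals are computed from the
draws themselves.

The three 0-5-month feeding categories are modelled through nested
cumulative quantities (exclusive ⊆ exclusive∪predominant ⊆ any
breastfeeding) and differenced per draw, which guarantees a coherent
exclusive/predominant/partial/none composition summing to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from ._rng import substream
from .harmonize import observation_logits
from .synthetic import CUMULATIVE_STREAMS, STREAMS

STAGE1_COVARIATES = ("education", "ln_gdp", "underweight", "tfr")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Stage1Fit:
    """Covariate OLS fit for one indicator/stream (logit scale)."""

    indicator: str
    params: pd.Series
    conf_int: pd.DataFrame
    results: object                 # statsmodels results (cluster-robust cov)
    predictions: pd.DataFrame       # country_id, year, pred_logit
    residuals: pd.DataFrame         # country_id, year, residual, national, logit_variance


@dataclass(frozen=True)
class STWeights:
    """Space-time weighting scheme for the stage-2 smoother.

    Time weight is tricube: (1 - (|Δyear|/bandwidth)^e)^e for |Δyear| <
    bandwidth, else 0. Space weights attenuate residuals borrowed from other
    countries in the same region / super-region (same country has weight 1).
    Wherever a country-year draws on both national and subnational residuals,
    the subnational mass is renormalized to 1 - national_data_share.
    """

    time_bandwidth: float = 10.0
    time_exponent: float = 3.0
    space_weight_region: float = 0.5
    space_weight_super_region: float = 0.25
    national_data_share: float = 0.9

    def __post_init__(self) -> None:
        if self.time_bandwidth <= 0:
            raise ValueError("time_bandwidth must be positive")
        if not (0.0 < self.space_weight_region < 1.0
                and 0.0 < self.space_weight_super_region < 1.0):
            raise ValueError("space weights must lie in (0, 1)")
        if not 0.5 < self.national_data_share <= 1.0:
            raise ValueError("national_data_share must be in (0.5, 1]")

    def time_weight(self, dyear) -> np.ndarray:
        u = np.abs(np.asarray(dyear, dtype=float)) / self.time_bandwidth
        w = np.where(u < 1.0, (1.0 - u ** self.time_exponent) ** self.time_exponent, 0.0)
        return w


@dataclass(frozen=True)
class GPRConfig:
    """Stage-3 Gaussian-process hyperparameters (logit scale).

    amplitude=None estimates the kernel amplitude per region from the median
    absolute deviation of the residuals around the stage-2 prior (scaled by
    1.4826, floored at amplitude_floor). nsv is a non-sampling variance floor
    added to every observation; non-national observations get
    subnational_extra_var on top, reflecting their unknown representativeness
    bias.
    """

    length_scale: float = 10.0
    amplitude: float | None = None
    amplitude_floor: float = 0.10
    nsv: float = 5e-4
    subnational_extra_var: float = 0.09
    n_draws: int = 1000
    jitter: float = 1e-10


@dataclass(frozen=True)
class PipelineConfig:
    st_weights: STWeights = field(default_factory=STWeights)
    gpr: GPRConfig = field(default_factory=GPRConfig)


class PrevalenceDraws:
    """Posterior draws for one indicator over a country x year grid.

    draws has shape (n_countries, n_years, n_draws) and holds proportions in
    [0, 1]. Means and 95% intervals are computed from the draws.
    """

    def __init__(self, indicator: str, countries: np.ndarray, years: np.ndarray,
                 draws: np.ndarray):
        self.indicator = indicator
        self.countries = np.asarray(countries)
        self.years = np.asarray(years)
        if draws.shape[:2] != (len(self.countries), len(self.years)):
            raise ValueError("draws shape does not match grid")
        self.draws = draws

    @property
    def n_draws(self) -> int:
        return self.draws.shape[2]

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=2)

    @property
    def lower_95(self) -> np.ndarray:
        return np.quantile(self.draws, 0.025, axis=2)

    @property
    def upper_95(self) -> np.ndarray:
        return np.quantile(self.draws, 0.975, axis=2)

    def summary(self) -> pd.DataFrame:
        nc, ny = len(self.countries), len(self.years)
        return pd.DataFrame({
            "country_id": np.repeat(self.countries, ny),
            "year": np.tile(self.years, nc),
            "indicator": self.indicator,
            "mean": self.mean.ravel(),
            "lower_95": self.lower_95.ravel(),
            "upper_95": self.upper_95.ravel(),
        })


# ---------------------------------------------------------------------------
# covariate screening
# ---------------------------------------------------------------------------

def screen_covariates(
    observations: pd.DataFrame,
    covariates: pd.DataFrame,
    candidates: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Rank candidate covariates by |Pearson r| with logit prevalence.

    Report only: the four fixed stage-1 covariates are used regardless of
    the ranking. Candidates with fewer than three paired points or constant
    values are skipped with a warning.
    """
    if candidates is None:
        candidates = tuple(c for c in covariates.columns
                           if c not in ("country_id", "year"))
    merged = observations.merge(covariates, on=["country_id", "year"], how="inner")
    lv, _ = observation_logits(merged)
    merged = merged.assign(_lv=lv)
    rows = []
    for indicator, sub in merged.groupby("indicator", sort=True):
        for cand in candidates:
            x = sub[cand].values
            y = sub["_lv"].values
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                warnings.warn(f"covariate {cand!r} skipped for {indicator}: "
                              f"<3 paired points", UserWarning, stacklevel=2)
                continue
            if np.std(x[ok]) <= 1e-12 * max(1.0, np.abs(np.mean(x[ok]))):
                warnings.warn(f"covariate {cand!r} skipped for {indicator}: "
                              f"constant", UserWarning, stacklevel=2)
                continue
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            rows.append({"indicator": indicator, "covariate": cand,
                         "r": r, "n": int(ok.sum())})
    report = pd.DataFrame(rows)
    if len(report):
        report["rank"] = (report.groupby("indicator")["r"]
                          .transform(lambda s: s.abs().rank(ascending=False)
                                     .astype(int)))
        report = report.sort_values(["indicator", "rank"]).reset_index(drop=True)
    return report


# ---------------------------------------------------------------------------
# stage 1: covariate OLS
# ---------------------------------------------------------------------------

def _collinear_columns(X: pd.DataFrame) -> list[str]:
    names = list(X.columns)
    bad = []
    for j, name in enumerate(names):
        if name == "const":
            continue
        others = X.drop(columns=[name]).values
        target = X[name].values
        beta, res_ss, *_ = np.linalg.lstsq(others, target, rcond=None)
        fitted = others @ beta
        ss = np.sum((target - fitted) ** 2)
        denom = np.sum((target - target.mean()) ** 2)
        if denom == 0 or ss / denom < 1e-10:
            bad.append(name)
    return bad


def _mixed_model_conf_int(merged: pd.DataFrame, y: np.ndarray,
                          geo: pd.DataFrame) -> pd.DataFrame | None:
    """95% intervals for the covariate effects from a nested REML model.

    Naive OLS intervals badly understate the uncertainty of country-level
    covariate effects here: residual variation is clustered at the country,
    region and super-region levels and countries carry random time trends.
    The intervals therefore come from a linear mixed model with
    super-region/region/country random intercepts and a country random
    trend, with a t reference on (number of regions - 1) degrees of freedom
    — a conservative small-sample choice given the few clusters at the top
    of the hierarchy. Returns None if no REML fit converges.
    """
    import statsmodels.formula.api as smf

    df = merged.merge(geo[["country_id", "region_id", "super_region_id"]]
                      .drop_duplicates(), on="country_id", how="left")
    if df["region_id"].isna().any():
        return None
    df = df.assign(_lv=y, _year_c=(df["year"] - df["year"].mean()) / 10.0,
                   _subnat=(~df["national"].astype(bool)).astype(float)
                   if "national" in df else 0.0)
    formula = "_lv ~ " + " + ".join(STAGE1_COVARIATES) + " + _subnat"
    n_regions = df["region_id"].nunique()
    tcrit = stats.t.ppf(0.975, max(n_regions - 1, 2))
    vc_full = {"region": "0 + C(region_id)", "country": "0 + C(country_id)",
               "ctrend": "0 + C(country_id):_year_c"}
    vc_simple = {"region": "0 + C(region_id)", "country": "0 + C(country_id)"}
    for vc in (vc_full, vc_simple):
        md = smf.mixedlm(formula, df, groups="super_region_id",
                         re_formula="1", vc_formula=vc)
        for method in ("lbfgs", "bfgs", "powell", "cg"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = md.fit(reml=True, method=method, maxiter=500)
            except Exception:
                continue
            bse = res.bse[list(STAGE1_COVARIATES)]
            if np.all(np.isfinite(bse)) and np.all(bse > 0):
                params = res.params[list(STAGE1_COVARIATES)]
                return pd.DataFrame({0: params - tcrit * bse,
                                     1: params + tcrit * bse})
    return None


def fit_stage1_ols(
    observations: pd.DataFrame,
    covariates: pd.DataFrame,
    indicator: str,
    geo: pd.DataFrame | None = None,
) -> Stage1Fit:
    """Fit the stage-1 OLS on the logit scale and predict all country-years.

    The regression includes the four covariates plus a subnational-survey
    indicator that absorbs the mean representativeness bias; predictions for
    the country-year surface are made at the national level (indicator = 0).
    Coefficient confidence intervals come from a nested random-effects model
    when ``geo`` is supplied (see :func:`_mixed_model_conf_int`), falling
    back to country-cluster-robust OLS intervals otherwise. Residuals are
    observed logit minus the national surface prediction for every in-sample
    point.
    """
    obs = observations[observations["indicator"] == indicator]
    if len(obs) < 10:
        raise PipelineError(
            f"stage1[{indicator}]: need >= 10 observations, got {len(obs)}")
    merged = obs.merge(covariates, on=["country_id", "year"], how="left",
                       validate="many_to_one")
    missing = merged[list(STAGE1_COVARIATES)].isna().any(axis=1)
    if missing.any():
        raise PipelineError(
            f"stage1[{indicator}]: covariates missing for "
            f"{int(missing.sum())} observation country-years")
    y, logit_var = observation_logits(merged)
    national = (merged["national"].astype(bool).values if "national" in merged
                else np.ones(len(merged), dtype=bool))
    X = sm.add_constant(merged[list(STAGE1_COVARIATES)], has_constant="add")
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        bad = _collinear_columns(X)
        raise PipelineError(
            f"stage1[{indicator}]: rank-deficient design; "
            f"collinear columns: {bad}")
    X = X.assign(subnational=(~national).astype(float))
    if X["subnational"].nunique() == 1:
        X = X.drop(columns=["subnational"])
    groups = merged["country_id"].astype("category").cat.codes.values
    model = sm.OLS(y, X)
    if len(np.unique(groups)) >= 2:
        results = model.fit(cov_type="cluster",
                            cov_kwds={"groups": groups}, use_t=True)
    else:
        results = model.fit(cov_type="HC1", use_t=True)

    conf_int = None
    if geo is not None:
        conf_int = _mixed_model_conf_int(merged, y, geo)
    if conf_int is None:
        conf_int = results.conf_int()

    beta = results.params
    grid = covariates[["country_id", "year"]].copy()
    Xg = sm.add_constant(covariates[list(STAGE1_COVARIATES)], has_constant="add")
    grid["pred_logit"] = Xg.values @ beta[Xg.columns].values
    fitted_national = X.drop(columns=["subnational"], errors="ignore").values \
        @ beta[[c for c in X.columns if c != "subnational"]].values
    residuals = pd.DataFrame({
        "country_id": merged["country_id"].values,
        "year": merged["year"].values,
        "residual": y - fitted_national,
        "national": national,
        "logit_variance": logit_var,
    })
    return Stage1Fit(
        indicator=indicator,
        params=results.params,
        conf_int=conf_int,
        results=results,
        predictions=grid,
        residuals=residuals,
    )


# ---------------------------------------------------------------------------
# stage 2: spatio-temporal residual smoothing
# ---------------------------------------------------------------------------

def _smooth_one_country(
    target_years: np.ndarray,
    obs_years: np.ndarray,
    obs_resid: np.ndarray,
    obs_national: np.ndarray,
    weights: STWeights,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-smoothed residual of one source country at each target year.

    Returns (rho, defined): rho is the tricube-weighted mean of the country's
    residuals, with national and subnational masses renormalized to
    national_data_share / (1 - national_data_share) when both are present;
    defined is False where no observation has positive time weight.
    """
    tw = weights.time_weight(target_years[:, None] - obs_years[None, :])
    nat = obs_national.astype(bool)
    m_nat = tw[:, nat].sum(axis=1)
    m_sub = tw[:, ~nat].sum(axis=1)
    s_nat = tw[:, nat] @ obs_resid[nat]
    s_sub = tw[:, ~nat] @ obs_resid[~nat]
    rho = np.zeros(len(target_years))
    defined = (m_nat > 0) | (m_sub > 0)
    both = (m_nat > 0) & (m_sub > 0)
    a = weights.national_data_share
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_both = a * s_nat / m_nat + (1 - a) * s_sub / m_sub
        rho_nat = s_nat / m_nat
        rho_sub = s_sub / m_sub
    rho[both] = rho_both[both]
    only_nat = (m_nat > 0) & ~both
    only_sub = (m_sub > 0) & ~both
    rho[only_nat] = rho_nat[only_nat]
    rho[only_sub] = rho_sub[only_sub]
    return rho, defined


def fit_stage2_st(
    stage1: Stage1Fit,
    geo: pd.DataFrame,
    weights: STWeights | None = None,
) -> pd.DataFrame:
    """Smooth stage-1 residuals over space and time.

    For a target country c, every source country j contributes its
    time-smoothed residual profile rho_j(t) with a space weight s_j of 1
    (j = c), space_weight_region (same region) or space_weight_super_region
    (same super-region). The prediction is

        sum_j s_j rho_j(t) / max(1, sum_j s_j over defined j),

    so residual information borrowed only from neighbours is attenuated
    toward zero rather than fully adopted. Returns a complete country-year
    frame with a ``smoothed_residual`` column (zero, with a warning, if no
    residuals exist at all).
    """
    if weights is None:
        weights = STWeights()
    res = stage1.residuals
    grid = stage1.predictions[["country_id", "year"]]
    years = np.sort(grid["year"].unique())
    countries = geo["country_id"].values
    region = dict(zip(geo["country_id"], geo["region_id"]))
    sregion = dict(zip(geo["country_id"], geo["super_region_id"]))

    if len(res) == 0:
        warnings.warn("stage 2: no residuals; returning zero surface",
                      UserWarning, stacklevel=2)
        out = grid.copy()
        out["smoothed_residual"] = 0.0
        return out

    profiles = {}
    for j, sub in res.groupby("country_id"):
        profiles[j] = _smooth_one_country(
            years, sub["year"].values.astype(float), sub["residual"].values,
            sub["national"].values, weights)

    rows = []
    for c in countries:
        num = np.zeros(len(years))
        den = np.zeros(len(years))
        for j, (rho, defined) in profiles.items():
            if j == c:
                s = 1.0
            elif region.get(j) == region.get(c):
                s = weights.space_weight_region
            elif sregion.get(j) == sregion.get(c):
                s = weights.space_weight_super_region
            else:
                continue
            num += np.where(defined, s * rho, 0.0)
            den += np.where(defined, s, 0.0)
        pred = num / np.maximum(1.0, den)
        rows.append(pd.DataFrame({"country_id": c, "year": years,
                                  "smoothed_residual": pred}))
    out = pd.concat(rows, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# stage 3: Gaussian process regression
# ---------------------------------------------------------------------------

def matern52(x1: np.ndarray, x2: np.ndarray, amplitude: float,
             length_scale: float) -> np.ndarray:
    """Matérn 5/2 covariance between two sets of time points."""
    d = np.abs(np.asarray(x1, dtype=float)[:, None]
               - np.asarray(x2, dtype=float)[None, :])
    u = np.sqrt(5.0) * d / length_scale
    return amplitude ** 2 * (1.0 + u + u ** 2 / 3.0) * np.exp(-u)


def _chol_with_jitter(K: np.ndarray, jitter: float) -> np.ndarray:
    j = jitter
    for _ in range(6):
        try:
            return np.linalg.cholesky(K + j * np.eye(len(K)))
        except np.linalg.LinAlgError:
            j *= 100.0
    raise np.linalg.LinAlgError(
        "non-positive-definite covariance after jitter escalation")


def _regional_amplitudes(
    prior: pd.DataFrame,
    observations: pd.DataFrame,
    geo: pd.DataFrame | None,
    config: GPRConfig,
) -> dict[str, float]:
    """Kernel amplitude per country from the MAD of prior residuals by region."""
    obs = observations.merge(prior, on=["country_id", "year"], how="left")
    lv, _ = observation_logits(obs)
    resid = lv - obs["prior_logit"].values
    global_amp = max(config.amplitude_floor,
                     1.4826 * float(np.median(np.abs(resid))) if len(resid) else 0.0)
    amps: dict[str, float] = {}
    countries = prior["country_id"].unique()
    if geo is None:
        return {c: global_amp for c in countries}
    region = dict(zip(geo["country_id"], geo["region_id"]))
    obs_region = obs["country_id"].map(region)
    for c in countries:
        mask = (obs_region == region.get(c)).values
        if mask.sum() >= 5:
            amp = 1.4826 * float(np.median(np.abs(resid[mask])))
            amps[c] = max(config.amplitude_floor, amp)
        else:
            amps[c] = global_amp
    return amps


def fit_stage3_gpr(
    prior: pd.DataFrame,
    observations: pd.DataFrame,
    config: GPRConfig | None = None,
    geo: pd.DataFrame | None = None,
    seed: int = 0,
    stream: str = "stream",
    indicator: str | None = None,
) -> PrevalenceDraws:
    """Per-country GP over years with the stage-1+2 surface as prior mean.

    ``prior`` must cover the full country-year grid with a ``prior_logit``
    column; ``observations`` carry value/sample_size/variance (logit stats
    are derived internally) plus the ``national`` flag. Observation noise is
    the logit-scale sampling variance plus the non-sampling floor, plus
    subnational_extra_var for non-national points. A country with no data
    gets the prior itself (mean and kernel covariance). Draws are sampled
    per country from a named substream, transformed to proportions.
    """
    if config is None:
        config = GPRConfig()
    indicator = indicator or stream
    years = np.sort(prior["year"].unique())
    countries = prior["country_id"].unique()
    if config.amplitude is not None:
        amps = {c: config.amplitude for c in countries}
    else:
        amps = _regional_amplitudes(prior, observations, geo, config)

    if len(observations):
        lv, lvar = observation_logits(observations)
        obs = observations.assign(_lv=lv, _lvar=lvar)
    else:
        obs = pd.DataFrame(columns=["country_id", "year", "national",
                                    "_lv", "_lvar"])

    prior_wide = prior.pivot_table(index="country_id", columns="year",
                                   values="prior_logit")
    draws = np.empty((len(countries), len(years), config.n_draws))
    for ci, c in enumerate(countries):
        m = prior_wide.loc[c, years].values.astype(float)
        sub = obs[obs["country_id"] == c]
        amp = amps[c]
        K_gg = matern52(years, years, amp, config.length_scale)
        if len(sub):
            t_o = sub["year"].values.astype(float)
            noise = (sub["_lvar"].values + config.nsv
                     + np.where(sub["national"].values.astype(bool), 0.0,
                                config.subnational_extra_var))
            K_oo = matern52(t_o, t_o, amp, config.length_scale) + np.diag(noise)
            K_go = matern52(years, t_o, amp, config.length_scale)
            L = _chol_with_jitter(K_oo, config.jitter)
            prior_at_obs = np.interp(t_o, years, m)
            alpha = np.linalg.solve(L.T, np.linalg.solve(L, sub["_lv"].values - prior_at_obs))
            post_mean = m + K_go @ alpha
            V = np.linalg.solve(L, K_go.T)
            post_cov = K_gg - V.T @ V
        else:
            post_mean = m
            post_cov = K_gg
        post_cov = 0.5 * (post_cov + post_cov.T)
        Lp = _chol_with_jitter(post_cov, config.jitter)
        rng = substream(seed, "gpr", stream, c)
        z = rng.standard_normal((len(years), config.n_draws))
        draws[ci] = expit(post_mean[:, None] + Lp @ z)
    return PrevalenceDraws(indicator, countries, years, draws)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def enforce_composition(
    cum_exclusive: np.ndarray,
    cum_excl_pred: np.ndarray,
    cum_any_bf: np.ndarray,
) -> dict[str, np.ndarray]:
    """Difference nested cumulative draws into coherent category shares.

    Inputs are aligned draw arrays of the three cumulative quantities
    (proportions). Per draw the three values are sorted (monotone
    rearrangement; GP draws are sampled independently so rare order
    violations are repaired) and differenced into exclusive, predominant,
    partial and none. Each share is >= 0 and the four sum to one exactly.
    """
    stacked = np.stack([cum_exclusive, cum_excl_pred, cum_any_bf], axis=-1)
    stacked = np.sort(stacked, axis=-1)
    c1, c2, c3 = stacked[..., 0], stacked[..., 1], stacked[..., 2]
    return {
        "exclusive_0_5": c1,
        "predominant_0_5": c2 - c1,
        "partial_0_5": c3 - c2,
        "none_0_5": 1.0 - c3,
    }


# ---------------------------------------------------------------------------
# composition observations + full pipeline
# ---------------------------------------------------------------------------

def build_stream_observations(observations: pd.DataFrame) -> pd.DataFrame:
    """Map harmonized indicator observations onto the six modelled streams.

    Initiation and the two continued indicators pass through. The three
    0-5-month categories of each survey are summed into the nested
    cumulative quantities; surveys missing any of the three categories are
    skipped for the cumulative streams.
    """
    direct = observations[observations["indicator"].isin(
        ("initiation_24h", "continued_6_11", "continued_12_23"))].copy()

    cats = observations[observations["indicator"].isin(
        ("exclusive_0_5", "predominant_0_5", "partial_0_5"))]
    frames = [direct]
    if len(cats):
        wide = cats.pivot_table(index="survey_id", columns="indicator",
                                values="value")
        complete = wide.dropna()
        meta = (cats.drop_duplicates("survey_id")
                .set_index("survey_id")
                .loc[complete.index,
                     ["country_id", "year", "sample_size", "national",
                      "standard_definition"]])
        infl = (cats.groupby("survey_id")["variance_inflation"].sum()
                if "variance_inflation" in cats
                else pd.Series(0.0, index=complete.index))
        cum = {
            "cum_exclusive": complete["exclusive_0_5"],
            "cum_excl_pred": complete["exclusive_0_5"] + complete["predominant_0_5"],
            "cum_any_bf": (complete["exclusive_0_5"] + complete["predominant_0_5"]
                           + complete["partial_0_5"]),
        }
        for stream, vals in cum.items():
            v = np.clip(vals.values, 0.0, 1.0)
            n = meta["sample_size"].values
            frames.append(pd.DataFrame({
                "survey_id": complete.index,
                "country_id": meta["country_id"].values,
                "year": meta["year"].values,
                "indicator": stream,
                "value": v,
                "sample_size": n,
                "variance": v * (1 - v) / n,
                "national": meta["national"].values,
                "standard_definition": meta["standard_definition"].values,
                "variance_inflation": infl.reindex(complete.index).fillna(0.0).values,
            }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class PipelineResult:
    """All artifacts of one three-stage run."""

    seed: int
    config: PipelineConfig
    stage1: dict[str, Stage1Fit]
    stage2: dict[str, pd.DataFrame]
    streams: dict[str, PrevalenceDraws]
    indicators: dict[str, PrevalenceDraws]
    composition: dict[str, np.ndarray]    # category draws incl. none_0_5
    countries: np.ndarray
    years: np.ndarray

    def estimates(self) -> pd.DataFrame:
        return pd.concat([d.summary() for d in self.indicators.values()],
                         ignore_index=True)

    def stage1_only_estimates(self) -> pd.DataFrame:
        """First-stage predictions alone, as proportions (for comparison)."""
        frames = []
        for stream, fit in self.stage1.items():
            f = fit.predictions.copy()
            f["indicator"] = stream
            f["mean"] = expit(f.pop("pred_logit"))
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def run_pipeline(
    observations: pd.DataFrame,
    covariates: pd.DataFrame,
    geo: pd.DataFrame,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run all three stages for every stream and assemble the six indicators.

    ``observations`` must already be harmonized (standard definitions only,
    or corrected). Produces a complete country x year x indicator grid of
    posterior draws; stage errors are re-raised with the stage identified.
    """
    if config is None:
        config = PipelineConfig()
    stream_obs = build_stream_observations(observations)
    stage1: dict[str, Stage1Fit] = {}
    stage2: dict[str, pd.DataFrame] = {}
    streams: dict[str, PrevalenceDraws] = {}
    for stream in STREAMS:
        try:
            # geo is not passed here: the pipeline consumes only the predicted
            # surface, and the mixed-model coefficient intervals are costly
            fit1 = fit_stage1_ols(stream_obs, covariates, stream)
            surf2 = fit_stage2_st(fit1, geo, config.st_weights)
            prior = fit1.predictions.merge(surf2, on=["country_id", "year"])
            prior["prior_logit"] = prior["pred_logit"] + prior["smoothed_residual"]
            sobs = stream_obs[stream_obs["indicator"] == stream]
            draws = fit_stage3_gpr(prior[["country_id", "year", "prior_logit"]],
                                   sobs, config.gpr, geo=geo, seed=seed,
                                   stream=stream)
        except PipelineError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError(f"pipeline stage failed for {stream}: {exc}") from exc
        stage1[stream] = fit1
        stage2[stream] = surf2
        streams[stream] = draws

    composition = enforce_composition(
        streams["cum_exclusive"].draws,
        streams["cum_excl_pred"].draws,
        streams["cum_any_bf"].draws,
    )
    countries = streams["cum_exclusive"].countries
    years = streams["cum_exclusive"].years
    indicators = {}
    for ind in ("exclusive_0_5", "predominant_0_5", "partial_0_5"):
        indicators[ind] = PrevalenceDraws(ind, countries, years, composition[ind])
    for ind in ("initiation_24h", "continued_6_11", "continued_12_23"):
        indicators[ind] = PrevalenceDraws(ind, streams[ind].countries,
                                          streams[ind].years, streams[ind].draws)
    return PipelineResult(seed=seed, config=config, stage1=stage1, stage2=stage2,
                          streams=streams, indicators=indicators,
                          composition=composition, countries=countries,
                          years=years)
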