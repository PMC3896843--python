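"""Attributable disease burden by comparative risk assessment.

Population attributable fractions (PAFs) compare the modelled distribution
of breastfeeding exposure categories against a theoretical-minimum-risk
counterfactual of full compliance with WHO recommendations (100% exclusive
breastfeeding under six months, 100% continued breastfeeding through 24
months):

    PAF = (sum_i P_i RR_i - sum_i P'_i RR_i) / (sum_i P_i RR_i)

Attributable deaths/DALYs are draw-level products of the PAF with
cause-specific background burden. Relative-risk uncertainty is propagated by
log-normal draws matched to the published 95% intervals; prevalence and RR
draws are paired by index. Timely initiation of breastfeeding is modelled
upstream but carries no burden, and discontinued breastfeeding has no
pneumonia outcome — both exclusions are enforced structurally.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .synthetic import YLL_PER_DEATH

AGE_0_5 = "0_5m"
AGE_6_23 = "6_23m"

#: Exposure categories per age group; the first is the reference (RR = 1).
CATEGORIES = {
    AGE_0_5: ("exclusive", "predominant", "partial", "none"),
    AGE_6_23: ("continued", "discontinued"),
}

OUTCOMES = ("diarrhea", "pneumonia")
METRICS = ("incidence", "mortality")

#: Pairs that must never produce burden cells.
EXCLUDED_PAIRS = {("discontinued", "pneumonia")}
EXCLUDED_EXPOSURES = {"initiation", "initiation_24h"}

Z975 = 1.959963984540054

#: Duration weights for combining the 6-11-month (6 months) and 12-23-month
#: (12 months) continued-breastfeeding indicators into the 6-23-month band.
CONTINUED_WEIGHTS = (6.0 / 18.0, 12.0 / 18.0)


@dataclass(frozen=True)
class EffectSize:
    """Relative risk with 95% CI for (exposure, age group, outcome, metric)."""

    exposure_category: str
    age_group: str
    outcome: str
    metric: str
    rr_mean: float
    rr_lower: float
    rr_upper: float

    def __post_init__(self) -> None:
        if not (self.rr_lower > 0 and self.rr_mean > 0 and self.rr_upper > 0):
            raise ValueError(f"non-positive relative risk in {self}")
        if not self.rr_lower <= self.rr_mean <= self.rr_upper:
            raise ValueError(
                f"CI ({self.rr_lower}, {self.rr_upper}) does not bracket "
                f"mean {self.rr_mean} for {self.exposure_category}/"
                f"{self.outcome}/{self.metric}")


def default_effect_sizes_path():
    """Path to the packaged effect-size table."""
    return importlib.resources.files("bfequity").joinpath("data/effect_sizes.csv")


def load_effect_sizes(source=None) -> dict[tuple, EffectSize]:
    """Load and validate effect sizes keyed by (exposure, age, outcome, metric).

    Validation: positive RRs with bracketing CIs; no initiation rows; no
    (discontinued, pneumonia) rows. An effect with a mortality estimate but
    no incidence estimate has the mortality value copied to incidence (the
    stated equal-effect assumption); if both are present for discontinued
    breastfeeding they must agree.
    """
    if source is None:
        source = default_effect_sizes_path()
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    effects: dict[tuple, EffectSize] = {}
    for _, row in df.iterrows():
        if row.exposure_category in EXCLUDED_EXPOSURES:
            raise ValueError(
                "late initiation of breastfeeding carries no attributable "
                "burden; remove the initiation row")
        if (row.exposure_category, row.outcome) in EXCLUDED_PAIRS:
            raise ValueError(
                "discontinued breastfeeding has no pneumonia outcome; "
                "remove the (discontinued, pneumonia) row")
        eff = EffectSize(row.exposure_category, row.age_group, row.outcome,
                         row.metric, float(row.rr_mean), float(row.rr_lower),
                         float(row.rr_upper))
        effects[(eff.exposure_category, eff.age_group, eff.outcome, eff.metric)] = eff
    # fill missing incidence from mortality
    for key in list(effects):
        cat, age, outcome, metric = key
        if metric != "mortality":
            continue
        inc_key = (cat, age, outcome, "incidence")
        if inc_key not in effects:
            m = effects[key]
            effects[inc_key] = EffectSize(cat, age, outcome, "incidence",
                                          m.rr_mean, m.rr_lower, m.rr_upper)
    return effects


def sample_rr_draws(effect: EffectSize, n_draws: int, seed: int) -> np.ndarray:
    """Log-normal RR draws: median = rr_mean, 2.5th/97.5th percentiles at the
    published CI bounds via sigma = ln(upper/lower) / (2 * 1.96). A degenerate
    CI (lower == upper) yields constant draws."""
    if effect.rr_lower == effect.rr_upper:
        return np.full(n_draws, effect.rr_mean)
    sigma = np.log(effect.rr_upper / effect.rr_lower) / (2.0 * Z975)
    rng = substream(seed, "rr", effect.exposure_category, effect.age_group,
                    effect.outcome, effect.metric)
    return np.exp(np.log(effect.rr_mean) + sigma * rng.standard_normal(n_draws))


def compute_paf(
    prevalence: dict[str, np.ndarray],
    relative_risks: dict[str, np.ndarray],
    counterfactual: dict[str, np.ndarray | float],
    tol: float = 1e-6,
) -> np.ndarray:
    """Exact PAF: (sum P_i RR_i - sum P'_i RR_i) / (sum P_i RR_i).

    All three mappings must share the same category keys, and both prevalence
    distributions must sum to one (per draw, within ``tol``). Values may be
    scalars or aligned draw vectors; the result is vectorized over draws.
    """
    cats = list(prevalence)
    if set(relative_risks) != set(cats) or set(counterfactual) != set(cats):
        raise ValueError(
            f"category mismatch: P={sorted(prevalence)}, "
            f"RR={sorted(relative_risks)}, P'={sorted(counterfactual)}")
    shape = np.broadcast_shapes(
        *(np.shape(prevalence[c]) for c in cats),
        *(np.shape(relative_risks[c]) for c in cats),
        *(np.shape(counterfactual[c]) for c in cats))
    P = np.stack([np.broadcast_to(np.asarray(prevalence[c], dtype=float), shape)
                  for c in cats])
    Pp = np.stack([np.broadcast_to(np.asarray(counterfactual[c], dtype=float),
                                   shape) for c in cats])
    RR = np.stack([np.broadcast_to(np.asarray(relative_risks[c], dtype=float),
                                   shape) for c in cats])
    if np.any(np.abs(P.sum(axis=0) - 1.0) > tol):
        raise ValueError("prevalence categories do not sum to 1")
    if np.any(np.abs(Pp.sum(axis=0) - 1.0) > tol):
        raise ValueError("counterfactual categories do not sum to 1")
    num = (P * RR).sum(axis=0) - (Pp * RR).sum(axis=0)
    den = (P * RR).sum(axis=0)
    return num / den


def reference_counterfactual(age_group: str) -> dict[str, float]:
    """Degenerate counterfactual: everyone in the reference category."""
    cats = CATEGORIES[age_group]
    return {c: (1.0 if c == cats[0] else 0.0) for c in cats}


def attributable_burden(paf_draws: np.ndarray, background: float) -> dict:
    """Draw-level attributable burden for one cell.

    Returns paf and attributable summaries (mean and 2.5/97.5 percentiles).
    """
    if background < 0:
        raise ValueError(f"negative background burden: {background}")
    paf_draws = np.asarray(paf_draws, dtype=float)
    att = paf_draws * background
    return {
        "paf_mean": float(paf_draws.mean()),
        "paf_lower": float(np.quantile(paf_draws, 0.025)),
        "paf_upper": float(np.quantile(paf_draws, 0.975)),
        "attributable_mean": float(att.mean()),
        "attributable_lower": float(np.quantile(att, 0.025)),
        "attributable_upper": float(np.quantile(att, 0.975)),
    }


# ---------------------------------------------------------------------------
# full burden run
# ---------------------------------------------------------------------------

@dataclass
class BurdenTable:
    """Draw-aligned burden cells: metadata rows plus a draws matrix."""

    meta: pd.DataFrame             # country_id, year, age_group, outcome, metric
    draws: np.ndarray              # (n_cells, n_draws) attributable values

    def summary(self) -> pd.DataFrame:
        out = self.meta.copy()
        out["mean"] = self.draws.mean(axis=1)
        out["lower_95"] = np.quantile(self.draws, 0.025, axis=1)
        out["upper_95"] = np.quantile(self.draws, 0.975, axis=1)
        return out


def exposure_distributions(result) -> dict[str, dict[str, np.ndarray]]:
    """Per-age-group category draws from a :class:`PipelineResult`.

    0-5 months: the coherent exclusive/predominant/partial/none composition.
    6-23 months: continued = duration-weighted mix of the 6-11 and 12-23
    indicators; discontinued is its complement.
    """
    comp = result.composition
    w611, w1223 = CONTINUED_WEIGHTS
    continued = (w611 * result.indicators["continued_6_11"].draws
                 + w1223 * result.indicators["continued_12_23"].draws)
    return {
        AGE_0_5: {
            "exclusive": comp["exclusive_0_5"],
            "predominant": comp["predominant_0_5"],
            "partial": comp["partial_0_5"],
            "none": comp["none_0_5"],
        },
        AGE_6_23: {
            "continued": continued,
            "discontinued": 1.0 - continued,
        },
    }


def run_burden(
    result,
    background: pd.DataFrame,
    effects: dict[tuple, EffectSize] | None = None,
    counterfactual: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, BurdenTable]:
    """Compute PAFs and attributable deaths/DALYs for every produced cell.

    ``background`` holds deaths and dalys per (country_id, year, cause,
    age_group). Attributable deaths apply the mortality PAF; DALYs are split
    into a YLL part (deaths x YLL_PER_DEATH, mortality PAF) and a YLD part
    (remainder, incidence PAF). Cells excluded by construction — anything
    involving timely initiation, and (discontinued, pneumonia), i.e. all
    pneumonia burden in the 6-23-month band — are never produced.

    Returns (paf table, attributable BurdenTable).
    """
    if effects is None:
        effects = load_effect_sizes()
    expo = exposure_distributions(result)
    countries = result.countries
    years = result.years
    n_draws = next(iter(result.indicators.values())).n_draws

    bg = background.set_index(["country_id", "year", "cause", "age_group"]).sort_index()

    paf_rows = []
    paf_draw_cache: dict[tuple, np.ndarray] = {}
    for age_group, cats in CATEGORIES.items():
        ref = cats[0]
        cf = (counterfactual or {}).get(age_group) or reference_counterfactual(age_group)
        for outcome in OUTCOMES:
            for metric in METRICS:
                keys = [(c, age_group, outcome, metric) for c in cats if c != ref]
                if not all(k in effects for k in keys):
                    continue  # structurally excluded (e.g. 6-23m pneumonia)
                rr = {ref: np.ones(n_draws)}
                for c in cats:
                    if c != ref:
                        rr[c] = sample_rr_draws(
                            effects[(c, age_group, outcome, metric)], n_draws, seed)
                for ci, country in enumerate(countries):
                    for yi, year in enumerate(years):
                        P = {c: expo[age_group][c][ci, yi, :] for c in cats}
                        paf = compute_paf(P, rr, cf)
                        paf_draw_cache[(country, int(year), age_group, outcome,
                                        metric)] = paf
                        paf_rows.append({
                            "country_id": country, "year": int(year),
                            "age_group": age_group, "outcome": outcome,
                            "metric": metric,
                            "paf_mean": paf.mean(),
                            "paf_lower": np.quantile(paf, 0.025),
                            "paf_upper": np.quantile(paf, 0.975),
                        })
    paf_table = pd.DataFrame(paf_rows)

    meta_rows = []
    draw_rows = []
    for (country, year, age_group, outcome, metric), paf in paf_draw_cache.items():
        if metric != "mortality":
            continue
        try:
            cell = bg.loc[(country, year, outcome, age_group)]
        except KeyError:
            continue
        deaths = float(cell["deaths"])
        dalys = float(cell["dalys"])
        if deaths < 0 or dalys < 0:
            raise ValueError(f"negative background burden for {country}/{year}/"
                             f"{outcome}/{age_group}")
        paf_inc = paf_draw_cache[(country, year, age_group, outcome, "incidence")]
        yll = min(deaths * YLL_PER_DEATH, dalys)
        yld = dalys - yll
        att_deaths = paf * deaths
        att_dalys = paf * yll + paf_inc * yld
        for metric_name, att in (("deaths", att_deaths), ("dalys", att_dalys)):
            meta_rows.append({"country_id": country, "year": year,
                              "age_group": age_group, "outcome": outcome,
                              "metric": metric_name})
            draw_rows.append(att)
    meta = pd.DataFrame(meta_rows)
    draws = np.vstack(draw_rows) if draw_rows else np.empty((0, n_draws))
    return paf_table, BurdenTable(meta=meta, draws=draws)


def aggregate_burden(
    table: BurdenTable,
    by: list[str],
    geo: pd.DataFrame | None = None,
) -> BurdenTable:
    """Sum attributable burden at draw level over the grouping ``by``.

    ``metric`` is always part of the grouping: summing deaths with DALYs is
    an error the function enforces by grouping on metric and refusing a
    ``by`` that excludes it while mixing metrics. Optionally joins the
    geography table first so ``region_id``/``super_region_id`` can be used.
    """
    meta = table.meta
    if geo is not None:
        meta = meta.merge(geo, on="country_id", how="left")
    if "metric" not in by:
        if meta["metric"].nunique() > 1:
            raise ValueError("refusing to sum across metrics "
                             "(deaths and DALYs in one group)")
        by = by + ["metric"]
    grouped = meta.groupby(by, sort=True).indices
    out_meta = []
    out_draws = []
    for key, idx in grouped.items():
        key = key if isinstance(key, tuple) else (key,)
        out_meta.append(dict(zip(by, key)))
        out_draws.append(table.draws[idx].sum(axis=0))
    return BurdenTable(meta=pd.DataFrame(out_meta), draws=np.vstack(out_draws))


def percent_of_total(
    attributable: BurdenTable,
    totals: pd.DataFrame,
    by: list[str],
) -> pd.DataFrame:
    """Attributable burden as percent of a total envelope, summarized.

    ``totals`` must carry the grouping columns plus a ``total`` column.
    """
    agg = aggregate_burden(attributable, by)
    merged = agg.meta.merge(totals, on=[c for c in by if c in totals.columns],
                            how="left")
    pct = 100.0 * agg.draws / merged["total"].values[:, None]
    out = merged.copy()
    out["pct_mean"] = pct.mean(axis=1)
    out["pct_lower"] = np.quantile(pct, 0.025, axis=1)
    out["pct_upper"] = np.quantile(pct, 0.975, axis=1)
    return out


def rank_risks(risk_table: pd.DataFrame, value_col: str = "attributable_dalys") -> pd.DataFrame:
    """Dense per-country ranking of risk factors by attributable DALYs.

    Ties are broken deterministically by risk name and flagged. Requires at
    least two risks per country.
    """
    df = risk_table.copy()
    out = []
    group_cols = [c for c in ("country_id", "year") if c in df.columns]
    for key, sub in df.groupby(group_cols, sort=True):
        if sub["risk"].nunique() < 2:
            raise ValueError(f"need >= 2 risks per country, got "
                             f"{sub['risk'].nunique()} for {key}")
        sub = sub.sort_values(["risk"]).sort_values(
            value_col, ascending=False, kind="stable")
        ranks = sub[value_col].rank(method="dense", ascending=False).astype(int)
        tied = sub[value_col].duplicated(keep=False)
        sub = sub.assign(rank=ranks.values, tied=tied.values)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def leading_risk_count(ranked: pd.DataFrame, risk: str) -> int:
    """Number of countries where ``risk`` ranks first."""
    first = ranked[(ranked["rank"] == 1) & (ranked["risk"] == risk)]
    return int(first["country_id"].nunique())
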