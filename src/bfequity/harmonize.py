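"""Harmonization of survey observations to the standard indicator definitions.

Non-standard-definition survey estimates are converted to the standard WHO
definitions through an additive shift on the logit scale, estimated from
country-years observed under both definitions (the crosswalk). Corrections
are indicator-specific pooled shifts by default; a pooled-across-indicators
mode is exposed for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

#: Proportions of exactly 0 or 1 are clamped to [1/(4n), 1 - 1/(4n)] before
#: the logit transform so all logits are finite.
CLAMP_FACTOR = 4.0


def clamp_proportion(p, sample_size):
    """Clamp proportions away from {0, 1} as a function of sample size."""
    n = np.asarray(sample_size, dtype=float)
    eps = 1.0 / (CLAMP_FACTOR * n)
    return np.clip(p, eps, 1.0 - eps)


def observation_logits(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Logit-scale values and delta-method variances for survey observations.

    var(logit p) ~= var(p) / (p(1-p))^2, evaluated at the clamped value; any
    `variance_inflation` column (added by :func:`apply_corrections`) is
    included in the returned variance.
    """
    p = clamp_proportion(df["value"].values, df["sample_size"].values)
    lv = logit(p)
    var = df["variance"].values / (p * (1 - p)) ** 2
    # floor at the clamped binomial variance so zero-variance rows stay usable
    floor = 1.0 / (df["sample_size"].values * p * (1 - p))
    var = np.maximum(var, floor * 1e-6)
    if "variance_inflation" in df:
        var = var + df["variance_inflation"].fillna(0.0).values
    return lv, var


@dataclass(frozen=True)
class CorrectionModel:
    """Additive logit-scale crosswalk for one indicator."""

    indicator: str
    additive_logit_shift: float
    shift_se: float
    n_pairs: int

    @property
    def usable(self) -> bool:
        return self.n_pairs >= 2


def estimate_correction_factors(observations: pd.DataFrame) -> dict[str, CorrectionModel]:
    """Estimate one CorrectionModel per indicator from paired country-years.

    For each indicator, country-years observed under both the standard and a
    non-standard definition contribute one pair: the difference
    logit(standard) - logit(non-standard), where each side is the
    precision-weighted mean over that country-year's observations. The shift
    is the precision-weighted mean of pair differences (weights = inverse
    delta-method variance of the difference) and its standard error comes
    from the weighted empirical spread of the differences — a perfectly
    systematic distortion therefore has se = 0.

    Indicators with fewer than two pairs get an unusable model; downstream,
    their non-standard observations are dropped rather than corrected.
    """
    models: dict[str, CorrectionModel] = {}
    for indicator, sub in observations.groupby("indicator", sort=True):
        sub = sub.copy()
        lv, var = observation_logits(sub)
        sub["_lv"], sub["_var"] = lv, var
        sides = {}
        for standard, flag_sub in sub.groupby("standard_definition"):
            w = 1.0 / flag_sub["_var"]
            grp = flag_sub.assign(_w=w, _wl=w * flag_sub["_lv"]).groupby(
                ["country_id", "year"]
            )
            agg = grp[["_w", "_wl"]].sum()
            sides[standard] = pd.DataFrame({
                "lv": agg["_wl"] / agg["_w"],
                "var": 1.0 / agg["_w"],
            })
        if True not in sides or False not in sides:
            models[indicator] = CorrectionModel(indicator, np.nan, np.nan, 0)
            continue
        pairs = sides[True].join(sides[False], how="inner",
                                 lsuffix="_std", rsuffix="_ns")
        m = len(pairs)
        if m < 2:
            models[indicator] = CorrectionModel(indicator, np.nan, np.nan, m)
            continue
        d = (pairs["lv_std"] - pairs["lv_ns"]).values
        w = 1.0 / (pairs["var_std"] + pairs["var_ns"]).values
        shift = float(np.sum(w * d) / np.sum(w))
        # weighted empirical standard error of the weighted mean
        se = float(np.sqrt(np.sum(w * (d - shift) ** 2)
                           / ((m - 1) * np.sum(w))))
        models[indicator] = CorrectionModel(indicator, shift, se, m)
    return models


def apply_corrections(
    observations: pd.DataFrame,
    models: dict[str, CorrectionModel],
) -> tuple[pd.DataFrame, list[str]]:
    """Correct non-standard observations; return (corrected table, drop log).

    Standard observations pass through unchanged. Non-standard observations
    with a usable model are shifted on the logit scale, re-flagged standard
    with ``corrected_flag=True``, and their logit-scale sampling variance is
    inflated by shift_se^2 (recorded in ``variance_inflation``). Rows already
    flagged corrected are never re-shifted, so the operation is idempotent.
    Non-standard observations without a usable model are dropped with a
    logged reason.
    """
    df = observations.copy()
    if "corrected_flag" not in df:
        df["corrected_flag"] = False
    if "variance_inflation" not in df:
        df["variance_inflation"] = 0.0

    drop_log: list[str] = []
    needs = (~df["standard_definition"]) & (~df["corrected_flag"])
    keep = np.ones(len(df), dtype=bool)
    for indicator, sub in df[needs].groupby("indicator", sort=True):
        idx = sub.index
        model = models.get(indicator)
        if model is None or not model.usable:
            keep[df.index.get_indexer(idx)] = False
            reason = ("no correction model" if model is None
                      else f"unusable model (n_pairs={model.n_pairs})")
            for _, row in sub.iterrows():
                drop_log.append(
                    f"dropped {row.survey_id}/{indicator} "
                    f"({row.country_id}, {row.year}): {reason}"
                )
                logger.info(drop_log[-1])
            continue
        p = clamp_proportion(sub["value"].values, sub["sample_size"].values)
        new_val = expit(logit(p) + model.additive_logit_shift)
        df.loc[idx, "value"] = new_val
        df.loc[idx, "variance"] = new_val * (1 - new_val) / sub["sample_size"].values
        df.loc[idx, "variance_inflation"] = (
            sub["variance_inflation"].values + model.shift_se ** 2
        )
        df.loc[idx, "standard_definition"] = True
        df.loc[idx, "corrected_flag"] = True
    return df[keep].reset_index(drop=True), drop_log
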