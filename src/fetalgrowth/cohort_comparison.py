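"""Country-vs-global and covariate-effect analyses.

Comparisons operate on two levels:

* chart level — quantile-quantile pairings of two charts' percentile curves
  (:func:`qq_compare`) and direct gram differences between sex-stratified
  EFW medians (:func:`sex_median_difference`);
* model level — delta-method confidence intervals for the difference
  between a country's retransformed percentile and the all-countries
  percentile at a gestational age (:func:`percentile_difference_ci`), and
  per-quantile covariate effect summaries expressed as percent change in
  EFW per stated unit (:func:`covariate_effect_table`).

The "global" curve is the share-weighted average over the country design
rows of the same joint model (countries included); a leave-one-out global
is available via ``exclude_country=True``.  No multiplicity adjustment is
applied — with many (tau, week, country) cells the joint confidence is
accordingly lower than the per-interval 95%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .chart_builder import GrowthChart, ModelFrame
from .errors import IncompatibleChartsError, InvalidParameterError
from .qr_engine import QuantileFit, wald_test

__all__ = ["PercentileDifference", "qq_compare", "percentile_difference_ci",
           "covariate_effect_table", "sex_median_difference"]

#: per-unit scale at which covariate effects are reported
_EFFECT_UNITS = {
    "sex_male": ("fetal sex (male vs female)", 1.0),
    "age_y": ("maternal age (+10 y)", 10.0),
    "height_cm": ("maternal height (+10 cm)", 10.0),
    "weight_kg": ("maternal weight (+10 kg)", 10.0),
    "parity": ("parity (parous vs nulliparous)", 1.0),
    "bmi": ("BMI (+1 kg/m^2)", 1.0),
}


@dataclass
class PercentileDifference:
    """Country-minus-global percentile difference with its 95% CI (grams)."""

    tau: float
    week: int
    country: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float


def _check_compatible(chart_a: GrowthChart, chart_b: GrowthChart) -> None:
    if chart_a.parameter != chart_b.parameter:
        raise IncompatibleChartsError(
            f"parameters differ: {chart_a.parameter} vs {chart_b.parameter}")
    if not np.array_equal(chart_a.weeks, chart_b.weeks):
        raise IncompatibleChartsError("week grids differ")


def qq_compare(chart_a: GrowthChart, chart_b: GrowthChart,
               percentiles=None) -> pd.DataFrame:
    """Paired (value_a, value_b) per percentile over the common week grid.

    These pairs are the data behind a quantile-quantile plot: identical
    charts fall on the diagonal; a uniform multiplicative offset falls on a
    line through the origin with that slope.
    """
    _check_compatible(chart_a, chart_b)
    if percentiles is None:
        common = sorted(set(chart_a.percentiles) & set(chart_b.percentiles))
    else:
        common = [float(p) for p in percentiles]
    rows = []
    for p in common:
        for w in chart_a.weeks:
            rows.append((p, int(w), chart_a.value_at(w, p),
                         chart_b.value_at(w, p)))
    return pd.DataFrame(rows, columns=["percentile", "week",
                                       "value_a", "value_b"])


def percentile_difference_ci(fit: QuantileFit, frame: ModelFrame,
                             country: str, week: int, *,
                             level: float = 0.95,
                             exclude_country: bool = False
                             ) -> PercentileDifference:
    """Delta-method CI for country-minus-global EFW percentile at a week.

    Both fitted values are retransformed from the log scale; the variance of
    the difference uses the gradient ``exp(x_c'b) x_c - exp(x_g'b) x_g``
    with the fit's asymptotic coefficient covariance.
    """
    if fit.cov is None:
        raise InvalidParameterError("fit has no covariance; estimate it first")
    if "country" not in frame.spec.covariates:
        raise InvalidParameterError("model has no country terms")
    ga_days = week * 7.0
    x_c = frame.row(ga_days, country=country)
    if exclude_country:
        shares = {k: v for k, v in frame.country_shares.items() if k != country}
        tot = sum(shares.values())
        x_g = np.sum([s / tot * frame.row(ga_days, country=k)
                      for k, s in shares.items()], axis=0)
    else:
        x_g = frame.global_row(ga_days)
    mu_c = float(np.exp(x_c @ fit.beta))
    mu_g = float(np.exp(x_g @ fit.beta))
    grad = mu_c * x_c - mu_g * x_g
    var = float(grad @ fit.cov @ grad)
    se = float(np.sqrt(max(var, 0.0)))
    zcrit = float(norm.ppf(0.5 + level / 2.0))
    est = mu_c - mu_g
    return PercentileDifference(tau=fit.tau, week=int(week), country=country,
                                estimate=est, se=se,
                                ci_low=est - zcrit * se,
                                ci_high=est + zcrit * se)


def covariate_effect_table(fits: list[QuantileFit], frame: ModelFrame
                           ) -> pd.DataFrame:
    """Per-quantile covariate effects as percent change in the response.

    For each fitted tau and each covariate column in the model, reports
    ``100 * (exp(unit * beta) - 1)`` (percent per stated unit: +10 y age,
    +10 cm height, +10 kg weight; category contrasts for sex and parity)
    with the single-coefficient Wald chi-square and p-value.  The percent
    effects are invariant to the GA centring constant.
    """
    names = list(frame.design.names)
    rows = []
    for fit in fits:
        for col, (label, unit) in _EFFECT_UNITS.items():
            if col not in names:
                continue
            j = names.index(col)
            beta = float(fit.beta[j])
            pct = 100.0 * (np.exp(unit * beta) - 1.0)
            contrast = np.zeros((1, len(names)))
            contrast[0, j] = 1.0
            chi, df, p = wald_test(fit, contrast)
            rows.append({"tau": fit.tau, "covariate": label, "column": col,
                         "log_effect_per_unit": unit * beta,
                         "percent_effect": pct,
                         "chi_square": chi, "df": df, "p": p})
    return pd.DataFrame(rows)


def sex_median_difference(chart_male: GrowthChart, chart_female: GrowthChart,
                          week: int, percentile: float = 50.0) -> float:
    """Male minus female chart value at (week, percentile), in grams."""
    _check_compatible(chart_male, chart_female)
    return (chart_male.value_at(week, percentile)
            - chart_female.value_at(week, percentile))
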