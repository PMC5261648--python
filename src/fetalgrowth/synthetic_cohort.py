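"""Synthetic multi-country longitudinal ultrasound cohorts.

The generator emulates the design of a ten-country fetal growth study:
~140 women per country, biometry visits scheduled at 14/18/24/28/32/36/40
weeks with +/-1 week jitter, triplicate measurements reduced to a median,
and attrition (missed visits, consent withdrawal, loss to follow-up).

The generative model for estimated fetal weight is quantile-parametrised so
its conditional quantiles are available in closed form for recovery tests:
each subject carries a latent uniform rank ``r`` (kept across visits, so
individuals track along centiles), and

    log EFW = m(g) + sigma * (z + c(ga) * z^2) + sum_k beta_k(r) * x_k + d_country

where ``g`` is centred GA in weeks, ``m`` is a cubic calibrated to the
bundled WHO EFW median column, ``z = Phi^{-1}(r)``, ``sigma`` is the
log-scale spread calibrated to the bundled quartiles, and the ``z^2`` term
(linear in GA) drives the quartile asymmetry drift of the EFW distribution
from slightly left-skewed early in gestation to clearly right-skewed at
term.  Covariate effects ``beta_k(r)`` vary linearly in the rank between a
lower-tail and an upper-tail magnitude (e.g. male fetuses ~3.5% heavier at
low quantiles, ~4.5% at high quantiles).  Because ``c`` is linear and ``m``
cubic in GA, every conditional log-quantile is exactly cubic in GA: the
chart-fitting model is well specified and closed-form truth
(:func:`true_quantile`) is recoverable.

Biometry (BPD/HC/AC/FL/HL) is decomposed from the target EFW by scaling
smooth GA median profiles (fitted to the bundled charts) by a common factor
solved through the Hadlock formula — a quadratic in the factor, solved in
closed form.  Only EFW-level truth is asserted in recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import ConfigError, GARangeError, InvalidParameterError

__all__ = ["SimConfig", "EffectProfile", "simulate_cohort", "true_quantile",
           "STUDY_COUNTRIES", "REFERENCE_COVARIATES"]

STUDY_COUNTRIES = ("Argentina", "Brazil", "D. R. Congo", "Denmark", "Egypt",
                   "France", "Germany", "India", "Norway", "Thailand")

#: covariate values at which the base median curve applies
REFERENCE_COVARIATES = {"sex": "female", "age": 28.0, "height": 163.0,
                        "weight": 61.0, "parity": 0}

_Z_CLIP = 4.5
_QUARTILE_Z = float(norm.ppf(0.75))


@dataclass(frozen=True)
class EffectProfile:
    """Percent effect per stated unit, interpolated linearly across quantiles."""

    low_pct: float   # effect at the lowest quantiles
    high_pct: float  # effect at the highest quantiles

    def log_effect(self, tau):
        lo = np.log1p(self.low_pct / 100.0)
        hi = np.log1p(self.high_pct / 100.0)
        return lo + np.asarray(tau, dtype=float) * (hi - lo)


def _default_country_effects() -> dict:
    # illustrative +/-5% multiplicative spread, ordered to echo the pattern
    # of country medians (India lowest, Norway highest)
    order = ("India", "Thailand", "Egypt", "D. R. Congo", "Brazil",
             "Argentina", "France", "Denmark", "Germany", "Norway")
    logs = np.linspace(np.log(0.95), np.log(1.05), len(order))
    return {c: float(v) for c, v in zip(order, logs)}


def _default_covariate_effects() -> dict:
    return {
        "sex": EffectProfile(3.5, 4.5),      # male vs female
        "age": EffectProfile(3.0, 2.0),      # per +10 y
        "height": EffectProfile(2.0, 1.0),   # per +10 cm
        "weight": EffectProfile(1.0, 1.5),   # per +10 kg
        "parity": EffectProfile(1.5, 1.0),   # parous vs nulliparous
    }


def _who_efw_calibration():
    """Cubic log-median coefficients, sigma and skew anchors from the
    bundled EFW chart."""
    from .reference_charts import load_bundle

    chart = load_bundle(verify=False).get("efw")
    g = chart.weeks.astype(float) - 27.0
    med = chart.values[:, np.flatnonzero(chart.percentiles == 50.0)[0]]
    q25 = chart.values[:, np.flatnonzero(chart.percentiles == 25.0)[0]]
    q75 = chart.values[:, np.flatnonzero(chart.percentiles == 75.0)[0]]
    coefs = np.polynomial.polynomial.polyfit(g, np.log(med), 3)
    sigma = float(np.mean((np.log(q75) - np.log(q25)) / (2.0 * _QUARTILE_Z)))
    return tuple(float(c) for c in coefs), sigma


def _bowley_of_skew(c: float, sigma: float) -> float:
    z = _QUARTILE_Z
    a = np.exp(sigma * (z + c * z * z))
    b = np.exp(sigma * (-z + c * z * z))
    return (a + b - 2.0) / (a - b)


def _solve_skew(target_bowley: float, sigma: float) -> float:
    return brentq(lambda c: _bowley_of_skew(c, sigma) - target_bowley,
                  -0.45, 0.45, xtol=1e-12)


@dataclass
class SimConfig:
    """Full generative specification for one synthetic cohort.

    Defaults reproduce the study design: ten countries of 140 women, seven
    scheduled visits with +/-1 wk jitter, 2% triplicate measurement CV,
    10% missed visits, 3.6% consent withdrawal, 3.2% loss to follow-up, and
    a quartile-asymmetry drift of the EFW distribution from Bowley -0.02 at
    15 wk to +0.11 at 40 wk.
    """

    n_per_country: int = 140
    countries: dict = field(default_factory=_default_country_effects)
    visit_weeks: tuple = (14, 18, 24, 28, 32, 36, 40)
    visit_jitter_weeks: float = 1.0
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    base_median_coefs: tuple | None = None   # ascending, log g at centred GA
    sigma: float | None = None               # log-scale spread
    bowley_15wk: float = -0.02
    bowley_40wk: float = 0.11
    measurement_cv: float = 0.02
    missed_visit_rate: float = 0.10
    withdrawal_rate: float = 0.036
    loss_rate: float = 0.032
    rank_tracking: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("measurement_cv", "missed_visit_rate",
                     "withdrawal_rate", "loss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.n_per_country < 1:
            raise ConfigError("n_per_country must be >= 1")
        if any(not 14 <= w < 41 for w in self.visit_weeks):
            raise ConfigError("visit weeks must lie within [14, 41)")
        if self.base_median_coefs is None or self.sigma is None:
            coefs, sigma = _who_efw_calibration()
            if self.base_median_coefs is None:
                self.base_median_coefs = coefs
            if self.sigma is None:
                self.sigma = sigma
        self.base_median_coefs = tuple(float(c) for c in self.base_median_coefs)
        self.sigma = float(self.sigma)
        # z^2 skew coefficient, linear in GA between the two anchors
        if self.sigma > 0:
            self._skew_15 = _solve_skew(self.bowley_15wk, self.sigma)
            self._skew_40 = _solve_skew(self.bowley_40wk, self.sigma)
        else:
            self._skew_15 = self._skew_40 = 0.0

    def skew_coef(self, ga_weeks):
        """z^2 coefficient at a GA (linear between the 15 and 40 wk anchors)."""
        w = np.asarray(ga_weeks, dtype=float)
        return self._skew_15 + (self._skew_40 - self._skew_15) * (w - 15.0) / 25.0

    def base_log_median(self, ga_days):
        g = np.asarray(ga_days, dtype=float) / 7.0 - 27.0
        return np.polynomial.polynomial.polyval(g, self.base_median_coefs)

    def log_quantile(self, ga_days, tau, country=None, covariates=None):
        """Closed-form log EFW quantile of the generative model (no window
        check; vectorised over ``ga_days`` and ``tau``)."""
        tau = np.asarray(tau, dtype=float)
        if np.any((tau <= 0) | (tau >= 1)):
            raise InvalidParameterError("tau must lie in (0,1)")
        cov = dict(REFERENCE_COVARIATES)
        cov.update(covariates or {})
        ga_days = np.asarray(ga_days, dtype=float)
        z = np.clip(norm.ppf(tau), -_Z_CLIP, _Z_CLIP)
        out = self.base_log_median(ga_days)
        out = out + self.sigma * (z + self.skew_coef(ga_days / 7.0) * z * z)
        eff = self.covariate_effects
        if "sex" in eff:
            male = np.asarray(cov["sex"]) == "male"
            out = out + eff["sex"].log_effect(tau) * male
        if "age" in eff:
            out = out + eff["age"].log_effect(tau) * (np.asarray(
                cov["age"], dtype=float) - 28.0) / 10.0
        if "height" in eff:
            out = out + eff["height"].log_effect(tau) * (np.asarray(
                cov["height"], dtype=float) - 163.0) / 10.0
        if "weight" in eff:
            out = out + eff["weight"].log_effect(tau) * (np.asarray(
                cov["weight"], dtype=float) - 61.0) / 10.0
        if "parity" in eff:
            out = out + eff["parity"].log_effect(tau) * (np.asarray(
                cov["parity"], dtype=float) > 0)
        if country is not None:
            if country not in self.countries:
                raise ConfigError(f"country {country!r} not in config")
            out = out + self.countries[country]
        return out


def true_quantile(config: SimConfig, ga_days, tau, country=None,
                  covariates=None):
    """Closed-form EFW quantile in grams; the ground-truth oracle.

    Strictly increasing in ``tau`` for every GA and covariate vector.
    Raises ``GARangeError`` outside gestational days 98-286.
    """
    ga = np.asarray(ga_days, dtype=float)
    if np.any((ga < 98) | (ga > 286)):
        raise GARangeError("gestational age outside days 98-286")
    res = np.exp(config.log_quantile(ga_days, tau, country=country,
                                     covariates=covariates))
    return float(res) if np.isscalar(tau) and np.isscalar(ga_days) else res


def _biometry_profiles():
    """Smooth log-scale cubic median profiles for each biometry parameter."""
    from .reference_charts import load_bundle

    bundle = load_bundle(verify=False)
    profiles = {}
    for param, col in (("bpd", "bpd_mm"), ("hc", "hc_mm"), ("ac", "ac_mm"),
                       ("fl", "fl_mm"), ("hl", "hl_mm")):
        chart = bundle.get(param)
        g = chart.weeks.astype(float) - 27.0
        med = chart.values[:, np.flatnonzero(chart.percentiles == 50.0)[0]]
        profiles[col] = np.polynomial.polynomial.polyfit(g, np.log(med), 3)
    return profiles


def _solve_hadlock_scale(hc_mm, ac_mm, fl_mm, target_g):
    """Common scale factor lam with Hadlock(hc*lam, ac*lam, fl*lam) = target.

    On the cm scale the Hadlock log10 is quadratic in lam,
    ``1.326 + b*lam - a*lam^2``; the increasing branch root is closed form.
    """
    hc, ac, fl = (np.asarray(v, dtype=float) / 10.0
                  for v in (hc_mm, ac_mm, fl_mm))
    a = 0.00326 * ac * fl
    b = 0.0107 * hc + 0.0438 * ac + 0.158 * fl
    d = np.log10(np.asarray(target_g, dtype=float)) - 1.326
    disc = b * b - 4.0 * a * d
    if np.any(disc <= 0):
        raise ConfigError("target EFW unreachable by uniform biometry scaling")
    return (b - np.sqrt(disc)) / (2.0 * a)


def simulate_cohort(config: SimConfig, seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; returns ``(subjects, scans)`` DataFrames.

    Bit-reproducible given the seed.  Withdrawn subjects contribute no
    scans; lost-to-follow-up subjects are truncated after a random visit;
    individual visits are missed independently.  Stored measurements are
    medians of three noisy acquisitions, rounded to 0.1 mm.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    countries = list(config.countries)
    n_total = config.n_per_country * len(countries)

    country_col = np.repeat(countries, config.n_per_country)
    age = np.clip(rng.normal(28.0, 4.45, n_total), 18, 40)
    height = np.clip(rng.normal(163.0, 8.2, n_total), 140, 185)
    weight = np.clip(np.exp(rng.normal(np.log(61.0), 0.157, n_total)), 40, 105)
    parity = (rng.random(n_total) < 0.42).astype(int)
    sex = np.where(rng.random(n_total) < 0.532, "male", "female")
    rank = rng.random(n_total)
    withdrawn = rng.random(n_total) < config.withdrawal_rate
    lost = rng.random(n_total) < config.loss_rate
    nv = len(config.visit_weeks)
    last_visit = np.where(lost, rng.integers(1, max(nv, 2), n_total), nv)

    subjects = pd.DataFrame({
        "subject_id": [f"S{i + 1:05d}" for i in range(n_total)],
        "country": country_col,
        "maternal_age_y": np.round(age, 1),
        "height_cm": np.round(height, 1),
        "weight_kg": np.round(weight, 1),
        "parity": parity,
        "fetal_sex": sex,
    })

    profiles = _biometry_profiles()
    rows = []
    sub_idx = []
    for j, week in enumerate(config.visit_weeks):
        attend = (~withdrawn) & (j < last_visit) \
                 & (rng.random(n_total) >= config.missed_visit_rate)
        idx = np.flatnonzero(attend)
        if idx.size == 0:
            continue
        jitter = rng.uniform(-config.visit_jitter_weeks,
                             config.visit_jitter_weeks, idx.size)
        ga_days = np.rint((week + jitter) * 7.0).astype(int)
        r = rank[idx] if config.rank_tracking else rng.random(idx.size)
        covs = {"sex": sex[idx], "age": age[idx], "height": height[idx],
                "weight": weight[idx], "parity": parity[idx]}
        logq = config.base_log_median(ga_days)
        z = np.clip(norm.ppf(r), -_Z_CLIP, _Z_CLIP)
        logq = logq + config.sigma * (z + config.skew_coef(ga_days / 7.0)
                                      * z * z)
        eff = config.covariate_effects
        if "sex" in eff:
            logq += eff["sex"].log_effect(r) * (covs["sex"] == "male")
        if "age" in eff:
            logq += eff["age"].log_effect(r) * (covs["age"] - 28.0) / 10.0
        if "height" in eff:
            logq += eff["height"].log_effect(r) * (covs["height"] - 163.0) / 10.0
        if "weight" in eff:
            logq += eff["weight"].log_effect(r) * (covs["weight"] - 61.0) / 10.0
        if "parity" in eff:
            logq += eff["parity"].log_effect(r) * (covs["parity"] > 0)
        logq += np.array([config.countries[c] for c in country_col[idx]])
        efw = np.exp(logq)

        g = ga_days / 7.0 - 27.0
        meds = {col: np.exp(np.polynomial.polynomial.polyval(g, coefs))
                for col, coefs in profiles.items()}
        lam = _solve_hadlock_scale(meds["hc_mm"], meds["ac_mm"],
                                   meds["fl_mm"], efw)
        clean = np.column_stack([meds[c] * lam for c in
                                 ("bpd_mm", "hc_mm", "ac_mm", "fl_mm", "hl_mm")])
        noise = rng.normal(0.0, config.measurement_cv, (idx.size, 5, 3))
        measured = clean * np.exp(np.median(noise, axis=2))
        rows.append(np.column_stack([ga_days, np.round(measured, 1)]))
        sub_idx.append(idx)

    if rows:
        allrows = np.vstack(rows)
        allsub = np.concatenate(sub_idx)
        scans = pd.DataFrame({
            "subject_id": subjects["subject_id"].to_numpy()[allsub],
            "ga_days": allrows[:, 0].astype(int),
            "bpd_mm": allrows[:, 1], "hc_mm": allrows[:, 2],
            "ac_mm": allrows[:, 3], "fl_mm": allrows[:, 4],
            "hl_mm": allrows[:, 5],
        })
        scans = (scans.drop_duplicates(subset=["subject_id", "ga_days"])
                 .sort_values(["subject_id", "ga_days"])
                 .reset_index(drop=True))
    else:
        scans = pd.DataFrame(columns=["subject_id", "ga_days", "bpd_mm",
                                      "hc_mm", "ac_mm", "fl_mm", "hl_mm"])
    return subjects, scans
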