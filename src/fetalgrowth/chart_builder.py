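"""Construction of fetal growth reference charts.

The pipeline mirrors the way distribution-free fetal references are built
from longitudinal ultrasound cohorts:

1. select the analysis window (gestational days 98-286, i.e. 14w+0d to
   40w+6d inclusive) and screen gross outliers with a running-median/MAD
   rule on the log scale;
2. regress the natural log of the parameter on a gestational-age polynomial
   (optionally with covariates, country indicators and GA x country
   interactions) separately at each quantile level, by pinball-loss
   minimisation (:mod:`fetalgrowth.qr_engine`);
3. evaluate the fitted log-quantile curves on a weekly grid, exponentiate
   back to the original scale, enforce within-week percentile ordering by
   monotone rearrangement, and round per parameter convention (mm and g to
   integers, ratios to two decimals).

Separate per-quantile fits need not be ordered; the rearrangement step is
idempotent and leaves already-monotone charts untouched, so it is safe to
apply unconditionally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import biometry
from .errors import (
    DegenerateSpreadError,
    InvalidParameterError,
    MissingCovariateError,
)
from .qr_engine import DesignMatrix, QuantileFit, fit_quantile_set

__all__ = [
    "QuantileModelSpec",
    "GrowthChart",
    "ModelFrame",
    "ChartFitResult",
    "DEFAULT_TAUS",
    "GA_WINDOW_DAYS",
    "GA_CENTER_WEEKS",
    "filter_analysis_set",
    "build_design",
    "construct_chart",
    "enforce_noncrossing",
    "bowley_coefficient",
]

#: default quantile grid: union of the figure percentiles and table columns
DEFAULT_TAUS = (0.01, 0.025, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95,
                0.975, 0.99)

#: analysis window, gestational days 14w+0d .. 40w+6d inclusive
GA_WINDOW_DAYS = (98, 286)

#: centring constant for the GA polynomial (conditioning only)
GA_CENTER_WEEKS = 27.0

_RESPONSES = {
    "bpd": ("bpd_mm", "mm"), "hc": ("hc_mm", "mm"), "ac": ("ac_mm", "mm"),
    "fl": ("fl_mm", "mm"), "hl": ("hl_mm", "mm"), "efw": ("efw_g", "g"),
    "fl_hc": ("fl_hc", ""), "fl_bpd": ("fl_bpd", ""),
    "birthweight": ("birthweight_g", "g"),
}

_COVARIATES = ("sex", "age", "height", "weight", "parity", "country", "bmi")


@dataclass(frozen=True)
class QuantileModelSpec:
    """What to fit: response, GA polynomial, covariates, quantile grid."""

    response: str = "efw"
    ga_degree: int = 3
    covariates: tuple[str, ...] = ()
    ga_by_country: bool = False
    taus: tuple[float, ...] = DEFAULT_TAUS

    def __post_init__(self):
        if self.response not in _RESPONSES:
            raise InvalidParameterError(f"unknown response {self.response!r}")
        if self.ga_degree < 1:
            raise InvalidParameterError("ga_degree must be >= 1")
        unknown = set(self.covariates) - set(_COVARIATES)
        if unknown:
            raise InvalidParameterError(f"unknown covariates: {sorted(unknown)}")
        taus = tuple(float(t) for t in self.taus)
        if any(not 0 < t < 1 for t in taus):
            raise InvalidParameterError("taus must lie in (0,1)")
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise InvalidParameterError("taus must be strictly increasing")
        if self.ga_by_country and "country" not in self.covariates:
            raise InvalidParameterError("ga_by_country requires 'country'")
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass
class GrowthChart:
    """A (week x percentile) matrix of reference values for one parameter."""

    parameter: str
    unit: str
    weeks: np.ndarray
    percentiles: np.ndarray
    values: np.ndarray
    provenance: str = "fitted"
    stratum: str | None = None

    def __post_init__(self):
        self.weeks = np.asarray(self.weeks, dtype=int)
        self.percentiles = np.asarray(self.percentiles, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.weeks.size, self.percentiles.size):
            raise InvalidParameterError("values shape must be (weeks, percentiles)")

    def value_at(self, week: int, percentile: float) -> float:
        iw = np.flatnonzero(self.weeks == week)
        ip = np.flatnonzero(np.isclose(self.percentiles, percentile))
        if iw.size == 0 or ip.size == 0:
            from .errors import OffGridError
            raise OffGridError(
                f"(week={week}, percentile={percentile}) not on the chart grid; "
                "use reference_charts.percentile_of for interpolation")
        return float(self.values[iw[0], ip[0]])

    def is_monotone_within_week(self) -> bool:
        return bool(np.all(np.diff(self.values, axis=1) >= 0))

    def to_csv(self, path_or_buf=None):
        """Chart as CSV: metadata comment, week column, ascending percentiles."""
        header = (f"# parameter={self.parameter},unit={self.unit},"
                  f"stratum={self.stratum or ''},provenance={self.provenance}")
        df = pd.DataFrame(self.values, columns=[_fmt_pct(p) for p in self.percentiles])
        df.insert(0, "week", self.weeks)
        if self.unit in ("mm", "g"):
            for c in df.columns[1:]:
                df[c] = df[c].round().astype(int)
        else:
            for c in df.columns[1:]:
                df[c] = df[c].round(2)
        buf = io.StringIO()
        buf.write(header + "\n")
        df.to_csv(buf, index=False)
        text = buf.getvalue()
        if path_or_buf is None:
            return text
        with open(path_or_buf, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_csv(cls, path_or_buf) -> "GrowthChart":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        lines = text.splitlines()
        meta = {}
        if lines and lines[0].startswith("#"):
            for kv in lines[0].lstrip("# ").split(","):
                k, _, v = kv.partition("=")
                meta[k.strip()] = v.strip()
        df = pd.read_csv(io.StringIO(text), comment="#")
        pcts = [float(c[1:]) for c in df.columns[1:]]
        return cls(parameter=meta.get("parameter", "unknown"),
                   unit=meta.get("unit", ""),
                   weeks=df["week"].to_numpy(),
                   percentiles=np.array(pcts),
                   values=df.iloc[:, 1:].to_numpy(dtype=float),
                   provenance=meta.get("provenance", "fitted"),
                   stratum=meta.get("stratum") or None)


def _fmt_pct(p: float) -> str:
    return f"p{p:g}"


def filter_analysis_set(scans: pd.DataFrame, *,
                        ga_window_days: tuple[int, int] = GA_WINDOW_DAYS,
                        outlier_k: float | None = 5.0,
                        bin_weeks: int = 2
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split scans into the analysis set and dropped rows with reasons.

    Scans outside the gestational window are dropped with reason
    ``ga-window``.  Within 2-week GA bins, a measurement whose log deviates
    from the bin median by more than ``outlier_k`` times the scaled MAD is
    dropped with reason ``outlier:<column>``; pass ``outlier_k=None`` to
    disable the screen.
    """
    if scans.empty:
        empty = scans.copy()
        dropped = empty.copy()
        dropped["reason"] = pd.Series(dtype=str)
        return empty, dropped
    lo, hi = ga_window_days
    ga = scans["ga_days"].to_numpy()
    reason = np.full(len(scans), "", dtype=object)
    out_window = (ga < lo) | (ga > hi)
    reason[out_window] = "ga-window"

    if outlier_k is not None:
        # residuals from a binned running median; the MAD scale is pooled
        # across bins (log-scale spread is near-homogeneous in GA, and
        # per-bin MADs are too noisy at typical per-bin counts)
        cols = [c for c in biometry.PHYSIOLOGICAL_RANGES_MM if c in scans.columns]
        bins = ga // (7 * bin_weeks)
        for col in cols:
            v = scans[col].to_numpy(dtype=float)
            logv = np.where(v > 0, np.log(np.where(v > 0, v, 1.0)), np.nan)
            resid = np.full(len(scans), np.nan)
            for b in np.unique(bins[~out_window]):
                idx = (bins == b) & ~out_window & np.isfinite(logv)
                if idx.sum() < 2:
                    continue
                resid[idx] = logv[idx] - np.median(logv[idx])
            ok = np.isfinite(resid)
            if not ok.any():
                continue
            mad = np.median(np.abs(resid[ok])) * 1.4826
            if mad <= 0:
                continue
            hit = ok & (np.abs(resid) > outlier_k * mad) & (reason == "")
            reason[hit] = f"outlier:{col}"

    keep = reason == ""
    kept = scans.loc[keep].copy()
    dropped = scans.loc[~keep].copy()
    dropped["reason"] = reason[~keep]
    return kept, dropped


@dataclass
class ModelFrame:
    """A fitted-model's design, response and the bookkeeping needed to
    evaluate it at new covariate values."""

    design: DesignMatrix
    y: np.ndarray
    spec: QuantileModelSpec
    ga_center: float
    country_levels: tuple[str, ...]
    country_shares: dict
    covariate_means: dict

    def row(self, ga_days: float, country: str | None = None,
            covariates: dict | None = None) -> np.ndarray:
        """Design row at a GA, a country level and covariate values.

        Continuous covariates default to their sample means, binary ones to
        their sample shares, so predictions are 'at the average subject'.
        """
        covariates = covariates or {}
        g = ga_days / 7.0 - self.ga_center
        vals = {"intercept": 1.0}
        for d in range(1, self.spec.ga_degree + 1):
            vals[f"ga{d}"] = g ** d
        for cov, col in (("sex", "sex_male"), ("age", "age_y"),
                         ("height", "height_cm"), ("weight", "weight_kg"),
                         ("parity", "parity"), ("bmi", "bmi")):
            if cov in self.spec.covariates:
                vals[col] = float(covariates.get(cov, self.covariate_means[col]))
        if "country" in self.spec.covariates:
            if country is not None and country not in self.country_levels:
                from .errors import UnknownStratumError
                raise UnknownStratumError(f"country {country!r} not in model")
            for lev in self.country_levels[1:]:
                ind = 1.0 if country == lev else 0.0
                vals[f"country[{lev}]"] = ind
                if self.spec.ga_by_country:
                    for d in range(1, self.spec.ga_degree + 1):
                        vals[f"ga{d}:country[{lev}]"] = vals[f"ga{d}"] * ind
        return np.array([vals[name] for name in self.design.names])

    def global_row(self, ga_days: float, covariates: dict | None = None
                   ) -> np.ndarray:
        """Share-weighted average of country rows: the all-countries curve."""
        if "country" not in self.spec.covariates:
            return self.row(ga_days, covariates=covariates)
        rows = [self.country_shares[lev] * self.row(ga_days, country=lev,
                                                    covariates=covariates)
                for lev in self.country_levels]
        return np.sum(rows, axis=0)


def build_design(scans: pd.DataFrame, subjects: pd.DataFrame,
                 spec: QuantileModelSpec,
                 ga_center_weeks: float = GA_CENTER_WEEKS) -> ModelFrame:
    """Assemble the log-scale response and the named design matrix.

    The response is the natural log of the requested parameter (derived
    quantities are computed on the fly).  GA enters in weeks, centred before
    polynomial expansion; country is indicator-coded against the first level
    in sorted order; interactions multiply the GA polynomial by the country
    indicators.
    """
    col, _unit = _RESPONSES[spec.response]
    scans = scans if col in scans.columns else biometry.add_derived_measures(scans)
    needed = {"sex": "fetal_sex", "age": "maternal_age_y", "height": "height_cm",
              "weight": "weight_kg", "parity": "parity", "country": "country"}
    use_cols = ["subject_id"] + sorted({needed[c] for c in spec.covariates
                                        if c in needed}
                                       | ({"height_cm", "weight_kg"}
                                          if "bmi" in spec.covariates else set()))
    if len(use_cols) > 1:
        missing_cols = [c for c in use_cols if c not in subjects.columns]
        if missing_cols:
            raise MissingCovariateError(f"subjects table lacks {missing_cols}")
        df = scans.merge(subjects[use_cols], on="subject_id",
                         how="left", validate="many_to_one")
        bad = df[use_cols[1:]].isna().any(axis=1)
        if bad.any():
            sid = df.loc[bad, "subject_id"].iloc[0]
            fld = df[use_cols[1:]].isna().any(axis=0)
            raise MissingCovariateError(
                f"subject {sid!r} is missing {list(fld[fld].index)}")
    else:
        df = scans.copy()

    y = np.log(df[col].to_numpy(dtype=float))
    g = df["ga_days"].to_numpy(dtype=float) / 7.0 - ga_center_weeks

    cols, names = [np.ones(len(df))], ["intercept"]
    for d in range(1, spec.ga_degree + 1):
        cols.append(g ** d)
        names.append(f"ga{d}")
    covariate_means: dict = {}
    if "sex" in spec.covariates:
        male = (df["fetal_sex"].astype(str).str.lower() == "male").to_numpy(float)
        cols.append(male); names.append("sex_male")
        covariate_means["sex_male"] = float(male.mean())
    if "age" in spec.covariates:
        v = df["maternal_age_y"].to_numpy(float)
        cols.append(v); names.append("age_y")
        covariate_means["age_y"] = float(v.mean())
    if "height" in spec.covariates:
        v = df["height_cm"].to_numpy(float)
        cols.append(v); names.append("height_cm")
        covariate_means["height_cm"] = float(v.mean())
    if "weight" in spec.covariates:
        v = df["weight_kg"].to_numpy(float)
        cols.append(v); names.append("weight_kg")
        covariate_means["weight_kg"] = float(v.mean())
    if "parity" in spec.covariates:
        v = (df["parity"].to_numpy(float) > 0).astype(float)
        cols.append(v); names.append("parity")
        covariate_means["parity"] = float(v.mean())
    if "bmi" in spec.covariates:
        v = df["weight_kg"].to_numpy(float) / (df["height_cm"].to_numpy(float)
                                               / 100.0) ** 2
        cols.append(v); names.append("bmi")
        covariate_means["bmi"] = float(v.mean())

    country_levels: tuple[str, ...] = ()
    country_shares: dict = {}
    if "country" in spec.covariates:
        country = df["country"].astype(str).to_numpy()
        country_levels = tuple(sorted(set(country)))
        n = len(df)
        country_shares = {lev: float((country == lev).sum()) / n
                          for lev in country_levels}
        for lev in country_levels[1:]:
            ind = (country == lev).astype(float)
            cols.append(ind); names.append(f"country[{lev}]")
            if spec.ga_by_country:
                for d in range(1, spec.ga_degree + 1):
                    cols.append(g ** d * ind)
                    names.append(f"ga{d}:country[{lev}]")

    design = DesignMatrix(np.column_stack(cols), tuple(names))
    return ModelFrame(design=design, y=y, spec=spec, ga_center=ga_center_weeks,
                      country_levels=country_levels,
                      country_shares=country_shares,
                      covariate_means=covariate_means)


@dataclass
class ChartFitResult:
    chart: GrowthChart
    fits: list[QuantileFit]
    frame: ModelFrame
    report: dict = field(default_factory=dict)


def construct_chart(scans: pd.DataFrame, subjects: pd.DataFrame,
                    spec: QuantileModelSpec, *,
                    weeks=None,
                    ga_window_days: tuple[int, int] = GA_WINDOW_DAYS,
                    outlier_k: float | None = 5.0,
                    country: str | None = None,
                    stratum: str | None = None,
                    round_values: bool = True,
                    compute_cov: bool = True) -> ChartFitResult:
    """Fit all quantile levels and evaluate them into a growth chart.

    ``country=None`` with a country model evaluates the share-weighted
    all-countries curve; naming a country evaluates that country's curve.
    Charts are evaluated at exact completed-week boundaries (week * 7 days).
    """
    weeks = np.arange(14, 41) if weeks is None else np.asarray(weeks, dtype=int)
    kept, dropped = filter_analysis_set(scans, ga_window_days=ga_window_days,
                                        outlier_k=outlier_k)
    if kept.empty:
        raise InvalidParameterError("no scans left after filtering")
    frame = build_design(kept, subjects, spec)
    n, p = frame.design.n, frame.design.p
    report = {"n_scans": int(n), "n_columns": int(p),
              "dropped": dropped["reason"].value_counts().to_dict()
              if len(dropped) else {},
              "taus": list(spec.taus)}
    if n < 50 * p:
        import warnings
        warnings.warn(f"only {n} scans for {p} design columns; "
                      "fits may be unstable", stacklevel=2)
    fits = fit_quantile_set(frame.design, frame.y, spec.taus,
                            compute_cov=compute_cov)
    report["objectives"] = [f.objective for f in fits]

    rows = np.stack([frame.row(w * 7.0, country=country) if country or not
                     frame.country_levels else frame.global_row(w * 7.0)
                     for w in weeks])
    values = np.exp(np.stack([rows @ f.beta for f in fits], axis=1))

    col, unit = _RESPONSES[spec.response]
    chart = GrowthChart(parameter=spec.response, unit=unit, weeks=weeks,
                        percentiles=np.array(spec.taus) * 100.0,
                        values=values, provenance="fitted",
                        stratum=stratum or country)
    chart = enforce_noncrossing(chart)
    if round_values:
        decimals = 0 if unit in ("mm", "g") else 2
        chart.values = np.round(chart.values, decimals)
    return ChartFitResult(chart=chart, fits=fits, frame=frame, report=report)


def enforce_noncrossing(chart: GrowthChart) -> GrowthChart:
    """Monotone rearrangement: sort values across percentiles within week.

    Idempotent; bit-identical on already-monotone charts.
    """
    return replace(chart, values=np.sort(chart.values, axis=1),
                   weeks=chart.weeks.copy(),
                   percentiles=chart.percentiles.copy())


def bowley_coefficient(q25: float, q50: float, q75: float) -> float:
    """Quartile skewness ((Q3-Q2)-(Q2-Q1))/(Q3-Q1), in [-1, 1].

    Zero for quartiles symmetric about the median; positive when the upper
    semi-quartile range exceeds the lower (right skew).  Invariant to affine
    maps of the quartiles with positive scale.
    """
    if not (q25 <= q50 <= q75):
        raise InvalidParameterError("quartiles must be ordered q25 <= q50 <= q75")
    if q75 == q25:
        raise DegenerateSpreadError("q25 == q75: quartile range is zero")
    return ((q75 - q50) - (q50 - q25)) / (q75 - q25)
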