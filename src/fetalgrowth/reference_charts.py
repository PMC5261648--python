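"""Bundled WHO fetal growth charts and clinical percentile lookup.

The published weekly reference tables (fetal biometry, EFW overall and by
fetal sex, FL/HC and FL/BPD ratios, and sex-specific birthweight) ship with
the package as plain CSV files plus a SHA-256 manifest, so the bundled data
are auditable byte for byte.  Lookup offers

* exact table cells (:func:`chart_value`, no interpolation), and
* clinical placement of a measurement (:func:`percentile_of`): linear
  interpolation in gestational age between adjacent week rows, then
  monotone piecewise-linear inversion across the percentile columns.

Values outside the printed percentile range are clamped to the boundary
percentile and flagged rather than extrapolated: tail extrapolation from a
printed grid has no statistical support.  The normal-equivalent z reported
alongside a percentile is a convenience for downstream software; the charts
themselves are distribution-free.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

from .chart_builder import GrowthChart
from .errors import (
    ChartIntegrityError,
    GARangeError,
    OffGridError,
    UnknownParameterError,
    UnknownStratumError,
)

__all__ = ["ChartBundle", "PercentilePlacement", "load_bundle", "chart_value",
           "percentile_of", "study_recruitment", "study_outcomes",
           "BUNDLE_VERSION"]

BUNDLE_VERSION = "WHO-FGC-2017/1"

# (parameter, stratum) -> bundled file
_CHART_FILES = {
    ("bpd", None): "who_fgc_bpd.csv",
    ("hc", None): "who_fgc_hc.csv",
    ("ac", None): "who_fgc_ac.csv",
    ("fl", None): "who_fgc_fl.csv",
    ("hl", None): "who_fgc_hl.csv",
    ("efw", None): "who_fgc_efw.csv",
    ("fl_hc", None): "who_fgc_fl_hc.csv",
    ("fl_bpd", None): "who_fgc_fl_bpd.csv",
    ("efw", "female"): "who_fgc_efw_female.csv",
    ("efw", "male"): "who_fgc_efw_male.csv",
    ("birthweight", "female"): "who_fgc_birthweight_female.csv",
    ("birthweight", "male"): "who_fgc_birthweight_male.csv",
}


@dataclass
class PercentilePlacement:
    """Placement of one measurement on a reference chart."""

    percentile: float
    z_equivalent: float
    flags: tuple[str, ...] = ()


@dataclass
class ChartBundle:
    charts: dict
    version: str = BUNDLE_VERSION
    extras: dict = field(default_factory=dict)

    def get(self, parameter: str, stratum: str | None = None) -> GrowthChart:
        key = (parameter, stratum)
        if key not in self.charts:
            if any(p == parameter for p, _ in self.charts):
                strata = sorted(s or "<none>" for p, s in self.charts
                                if p == parameter)
                raise UnknownStratumError(
                    f"{parameter!r} has strata {strata}, not {stratum!r}")
            raise UnknownParameterError(f"no bundled chart for {parameter!r}")
        return self.charts[key]


def _data_dir():
    return resources.files("fetalgrowth") / "data"


def _verify_checksums(data_dir) -> None:
    manifest = {}
    for line in (data_dir / "MANIFEST.sha256").read_text().splitlines():
        digest, _, name = line.strip().partition("  ")
        manifest[name] = digest
    for name, expect in manifest.items():
        got = hashlib.sha256((data_dir / name).read_bytes()).hexdigest()
        if got != expect:
            raise ChartIntegrityError(
                f"{name}: checksum mismatch (expected {expect[:12]}..., "
                f"got {got[:12]}...)")


def load_bundle(verify: bool = True) -> ChartBundle:
    """Load the bundled charts, verifying the checksum manifest by default."""
    data_dir = _data_dir()
    if verify:
        _verify_checksums(data_dir)
    charts = {}
    for (param, stratum), fname in _CHART_FILES.items():
        with (data_dir / fname).open() as fh:
            chart = GrowthChart.from_csv(fh)
        chart.provenance = "bundled-WHO"
        charts[(param, stratum)] = chart
    return ChartBundle(charts=charts)


def study_recruitment() -> pd.DataFrame:
    """Per-country recruitment, consent-withdrawal and discontinuation counts."""
    with (_data_dir() / "study_recruitment.csv").open() as fh:
        return pd.read_csv(fh)


def study_outcomes() -> pd.DataFrame:
    """Per-country preterm-birth counts and denominators."""
    with (_data_dir() / "study_outcomes.csv").open() as fh:
        return pd.read_csv(fh)


def chart_value(bundle: ChartBundle, parameter: str, week: int,
                percentile: float, stratum: str | None = None) -> float:
    """Exact printed table cell; off-grid requests raise ``OffGridError``."""
    return bundle.get(parameter, stratum).value_at(week, percentile)


def percentile_of(bundle: ChartBundle, parameter: str, ga_days: float,
                  value: float, stratum: str | None = None,
                  mode: str = "interpolate") -> PercentilePlacement:
    """Place a measurement on a chart at an arbitrary gestational age.

    ``mode='interpolate'`` (default) interpolates linearly in GA between the
    bracketing week rows; ``mode='completed-week'`` snaps GA down to the
    completed week.  The percentile is found by piecewise-linear inversion
    of the within-week value/percentile profile; out-of-range values return
    the boundary percentile flagged ``below-min``/``above-max``.
    """
    chart = bundle.get(parameter, stratum)
    if mode not in ("interpolate", "completed-week"):
        raise ValueError(f"unknown mode {mode!r}")
    ga_weeks = float(ga_days) / 7.0
    if mode == "completed-week":
        ga_weeks = float(np.floor(ga_weeks))
    wmin, wmax = chart.weeks.min(), chart.weeks.max()
    if not wmin <= ga_weeks <= wmax:
        raise GARangeError(
            f"gestational age {ga_days} d ({ga_weeks:.2f} wk) outside the "
            f"{parameter} chart range {wmin}-{wmax} wk")
    # linear interpolation of each percentile curve in GA
    row = np.array([np.interp(ga_weeks, chart.weeks, chart.values[:, j])
                    for j in range(chart.percentiles.size)])
    flags: list[str] = []
    if value <= row[0]:
        pct = float(chart.percentiles[0])
        if value < row[0]:
            flags.append("below-min")
    elif value >= row[-1]:
        pct = float(chart.percentiles[-1])
        if value > row[-1]:
            flags.append("above-max")
    else:
        pct = float(np.interp(value, row, chart.percentiles))
    return PercentilePlacement(percentile=pct,
                               z_equivalent=float(norm.ppf(pct / 100.0)),
                               flags=tuple(flags))
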