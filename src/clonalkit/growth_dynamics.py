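"""Tumor-burden and proliferation summaries.

Blood Gaussia luciferase (Gluc) activity proxies total tumor burden; per
mouse it is reported as fold change over the 24 h post-injection
baseline.  Doubling time in culture assumes exponential growth between
two counts.  The mesothelial clearance assay is summarized by the
cleared area at 24 h divided by the initial (1 h) spheroid cluster area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GlucSeries",
    "fold_change",
    "doubling_time",
    "linear_fit",
    "clearance_ratio",
    "background_level",
]


@dataclass
class GlucSeries:
    """One mouse's luciferase time course.

    The first time point is the 24 h post-injection baseline.
    ``background`` is the assay background level, e.g. from
    negative-control blood via :func:`background_level`.
    """

    mouse_id: str
    times: list[float]  # weeks; first entry is the 24 h baseline
    readings: list[float]  # relative light units
    background: float = 0.0

    def __post_init__(self) -> None:
        if len(self.times) != len(self.readings):
            raise ValueError("times and readings must have equal length")
        if any(r < 0 for r in self.readings):
            raise ValueError("luciferase readings must be >= 0")
        if not self.readings:
            raise ValueError("series must contain the baseline point")

    @property
    def baseline(self) -> float:
        return self.readings[0]


def background_level(control_readings: list[float], n_sd: float = 2.0) -> float:
    """Background threshold from negative-control readings: mean + n_sd * SD."""
    arr = np.asarray(control_readings, dtype=float)
    if arr.size == 0:
        raise ValueError("no control readings")
    return float(arr.mean() + n_sd * arr.std(ddof=1 if arr.size > 1 else 0))


def fold_change(series: GlucSeries) -> tuple[list[float], list[bool]]:
    """Per-timepoint fold change over the 24 h baseline.

    Returns (fold_changes, below_background_flags); a flagged point's
    raw reading is at or below the background level, but its fold change
    is still reported.

    Raises
    ------
    ValueError
        If the baseline reading is not positive.
    """
    if series.baseline <= 0:
        raise ValueError("baseline (24 h) reading must be > 0")
    folds = [r / series.baseline for r in series.readings]
    flags = [r <= series.background for r in series.readings]
    return folds, flags


def doubling_time(count_day1: float, count_day5: float, duration_h: float = 96.0) -> float:
    """Population doubling time in hours, assuming exponential growth.

    generations = log2(count_day5 / count_day1); doubling time =
    duration_h / generations.  Invariant to rescaling both counts.

    Raises
    ------
    ValueError
        If either count is non-positive, or the culture did not grow
        (count_day5 <= count_day1 leaves the doubling time undefined).
    """
    if count_day1 <= 0 or count_day5 <= 0:
        raise ValueError("cell counts must be > 0")
    if count_day5 <= count_day1:
        raise ValueError("no growth between counts: doubling time undefined")
    generations = math.log2(count_day5 / count_day1)
    return duration_h / generations


def linear_fit(x, y) -> tuple[float, float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R^2, two-tailed p).

    R^2 is the squared Pearson correlation; the p value comes from the
    slope's t statistic.  A constant y yields R^2 = 0 (and p = 1).

    Raises
    ------
    ValueError
        If fewer than 3 points or x is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    if np.ptp(y) == 0:
        slope, intercept = 0.0, float(y[0])
        return slope, intercept, 0.0, 1.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


def clearance_ratio(cleared_area_24h: float, initial_cluster_area_1h: float) -> float:
    """Mesothelial clearance: cleared area normalized to the initial area.

    Raises
    ------
    ValueError
        If the initial (1 h) cluster area is not positive.
    """
    if initial_cluster_area_1h <= 0:
        raise ValueError("initial cluster area must be > 0")
    if cleared_area_24h < 0:
        raise ValueError("cleared area must be >= 0")
    return cleared_area_24h / initial_cluster_area_1h
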