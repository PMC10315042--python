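"""In-vitro functional readouts: wound closure, proliferation-rate ratios,
proliferation-normalized invasion, and CCK8 growth summaries.

Scratch (wound-healing) assays report the percent of the initial wound area
closed by time t.  Transwell invasion counts confound invasiveness with
proliferation when the compared conditions grow at different rates, so the
invaded-cell count is divided by the proliferation-rate ratio
(test condition over reference condition) before comparison.  Proliferation
rates come from CCK8 absorbance time courses as the log-linear growth-phase
slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthSummary",
    "wound_closure",
    "proliferation_ratio",
    "normalized_invasion",
    "growth_fold_change",
]


@dataclass
class GrowthSummary:
    """Per-condition CCK8 time-course summary."""

    timepoints_h: np.ndarray = field(repr=False)
    fold_change: np.ndarray = field(repr=False)  # A(t) / A(0)
    rate_per_h: float  # log-linear slope, 1/h


def wound_closure(area_t0: float, area_t: float) -> float:
    """Percent of the initial scratch area closed: 100 * (A0 - At) / A0.

    Negative values (the wound widened) are allowed with a warning; closure
    cannot exceed 100% for non-negative areas.
    """
    if not area_t0 > 0:
        raise ValueError(f"initial wound area must be positive, got {area_t0}")
    if area_t < 0:
        raise ValueError(f"wound area cannot be negative, got {area_t}")
    closure = 100.0 * (area_t0 - area_t) / area_t0
    if closure < 0:
        warnings.warn("wound widened between timepoints (negative closure)", stacklevel=2)
    return closure


def proliferation_ratio(rate_test: float, rate_ref: float) -> float:
    """Ratio of proliferation rates, test condition over reference.

    E.g. cells in stiffer over softer matrices, or control over knockdown.
    """
    if not (rate_test > 0 and rate_ref > 0):
        raise ValueError("proliferation rates must be positive")
    return rate_test / rate_ref


def normalized_invasion(invaded_count: float, prolif_ratio: float) -> float:
    """Invaded-cell count corrected for a proliferation advantage.

    Dividing by the proliferation-rate ratio removes the part of a raw
    invasion excess that is explained by faster growth alone: a condition
    invading 2x more while proliferating 2x faster normalizes to parity.
    """
    if invaded_count < 0:
        raise ValueError(f"invaded count cannot be negative, got {invaded_count}")
    if not prolif_ratio > 0:
        raise ValueError(f"proliferation ratio must be positive, got {prolif_ratio}")
    return invaded_count / prolif_ratio


def growth_fold_change(timepoints_h, absorbance) -> GrowthSummary:
    """Fold change vs t0 and log-linear growth rate from a CCK8 time course.

    Parameters
    ----------
    timepoints_h : array-like
        Sampling times in hours; must include 0 and at least one later point.
    absorbance : array-like
        Background-corrected absorbance per timepoint; the baseline must be
        positive.

    The rate is the ordinary least-squares slope of log A(t) on t over all
    timepoints (a flat series gives rate 0; exact doubling every 24 h gives
    ln 2 / 24 per hour).  Non-positive absorbances beyond baseline make the
    log undefined and are rejected.
    """
    t = np.asarray(timepoints_h, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if t.shape != a.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("need matching 1-D time and absorbance arrays with >= 2 points")
    order = np.argsort(t)
    t, a = t[order], a[order]
    if t[0] != 0.0:
        raise ValueError("time course must include the t = 0 baseline")
    if a[0] <= 0:
        raise ValueError(f"baseline absorbance must be positive, got {a[0]}")
    if np.any(a <= 0):
        raise ValueError("absorbance must be positive at every timepoint to fit a growth rate")
    slope = np.polyfit(t, np.log(a), 1)[0]
    return GrowthSummary(timepoints_h=t, fold_change=a / a[0], rate_per_h=float(slope))
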