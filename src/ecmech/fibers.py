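"""Collagen fiber alignment quantification from per-field angle measurements.

Picrosirius-red-stained sections imaged under polarized light reveal type I
collagen fibers; the orientation of each fiber is recorded as an angle in
degrees against a horizontal reference.  Fiber orientations are *axial*
(undirected): a fiber at 10 degrees and one at 190 degrees are the same
fiber, so all angles live on [0, 180).

The per-field statistic is the alignment index

    AI = (1/N) * sum_i cos^2(theta_i - theta_median)

where ``theta_median`` is the ordinary (linear) median of the measured
angles.  AI = 1 for perfectly aligned fibers; for uniformly random
orientations AI concentrates at E[cos^2] = 0.5.  ``cos^2`` has period 180
degrees, so the axial wrap in the difference needs no special handling, but
AI is *not* invariant under rotations that push angles across the 0/180
boundary (the linear median moves discontinuously); this mirrors the manual
measurement protocol, where all angles are read against a fixed horizontal
line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FiberField",
    "CaseAlignment",
    "alignment_index",
    "nematic_order",
    "case_alignment",
    "compare_groups",
    "MIN_FIBERS_PER_FIELD",
    "MIN_FIELDS_PER_CASE",
]

#: protocol guideline: at least this many fibers measured per field
MIN_FIBERS_PER_FIELD = 20
#: protocol guideline: fields analyzed per case
MIN_FIELDS_PER_CASE = 3


def reduce_axial(angles_deg) -> np.ndarray:
    """Reduce arbitrary real angles to the axial domain [0, 180)."""
    return np.asarray(angles_deg, dtype=float) % 180.0


@dataclass
class FiberField:
    """One microscope field's measured fiber angles with case/group labels.

    Angles are reduced mod 180 on construction.  ``low_count`` flags fields
    with fewer than ``MIN_FIBERS_PER_FIELD`` measured fibers; such fields are
    analysed but the flag propagates to results.
    """

    case_id: str
    group: str
    field_id: str
    angles_deg: np.ndarray = field(repr=False)

    def __post_init__(self):
        angles = reduce_axial(self.angles_deg)
        if angles.ndim != 1 or angles.size < 1:
            raise ValueError("a field needs at least one measured fiber angle")
        self.angles_deg = angles

    @property
    def n_fibers(self) -> int:
        return int(self.angles_deg.size)

    @property
    def low_count(self) -> bool:
        return self.n_fibers < MIN_FIBERS_PER_FIELD

    @property
    def alignment_index(self) -> float:
        return alignment_index(self.angles_deg)


@dataclass
class CaseAlignment:
    """Per-case aggregation: field-level AIs and their unweighted mean."""

    case_id: str
    group: str
    field_ids: list[str]
    field_ai: list[float]
    mean_ai: float
    few_fields: bool  # fewer than MIN_FIELDS_PER_CASE fields analysed
    any_low_count: bool


def alignment_index(angles_deg) -> float:
    """Alignment index of one field: mean of cos^2(theta_i - theta_median).

    Parameters
    ----------
    angles_deg : array-like
        Fiber angles in degrees; reduced mod 180 before use.

    Returns
    -------
    float in [0, 1].  1 means all fibers share one orientation.
    """
    angles = reduce_axial(angles_deg)
    if angles.size == 0:
        raise ValueError("alignment index of an empty field is undefined")
    med = np.median(angles)
    dev = np.radians(angles - med)
    return float(np.mean(np.cos(dev) ** 2))


def nematic_order(angles_deg) -> float:
    """Order parameter 2*AI - 1, rescaled so uniform orientations give ~0.

    Offered as a clearly-labelled alternative readout; the primary statistic
    everywhere in this package is ``alignment_index``.
    """
    return 2.0 * alignment_index(angles_deg) - 1.0


def case_alignment(fields: list[FiberField]) -> list[CaseAlignment]:
    """Aggregate field-level alignment indices into per-case means.

    Fields are grouped by ``case_id``; the case value is the unweighted mean
    of its field AIs.  A warning is emitted (and flagged in the result) when
    a case has fewer than ``MIN_FIELDS_PER_CASE`` fields.
    """
    if not fields:
        raise ValueError("no fields supplied")
    by_case: dict[str, list[FiberField]] = {}
    order: list[str] = []
    for f in fields:
        if f.case_id not in by_case:
            by_case[f.case_id] = []
            order.append(f.case_id)
        by_case[f.case_id].append(f)

    results = []
    for case_id in order:
        fs = by_case[case_id]
        groups = {f.group for f in fs}
        if len(groups) != 1:
            raise ValueError(f"case {case_id!r} has inconsistent group labels: {groups}")
        ais = [f.alignment_index for f in fs]
        few = len(fs) < MIN_FIELDS_PER_CASE
        if few:
            warnings.warn(
                f"case {case_id!r}: only {len(fs)} field(s) analysed "
                f"(protocol guideline is {MIN_FIELDS_PER_CASE})",
                stacklevel=2,
            )
        results.append(
            CaseAlignment(
                case_id=case_id,
                group=fs[0].group,
                field_ids=[f.field_id for f in fs],
                field_ai=ais,
                mean_ai=float(np.mean(ais)),
                few_fields=few,
                any_low_count=any(f.low_count for f in fs),
            )
        )
    return results


def compare_groups(values_a, values_b, method: str = "t") -> tuple[float, float]:
    """Two-sided two-group comparison of scalar readouts.

    ``method="t"`` is the classical two-sample pooled-variance Student
    t-test; ``method="wilcoxon"`` is the unpaired Wilcoxon rank-sum
    (Mann-Whitney) test, exact when the combined sample is small (<= 20)
    and tie-free, normal approximation with tie correction otherwise.

    Returns ``(statistic, pvalue)``.  Degenerate t-test inputs (zero pooled
    variance) return p = 1 for equal means and p = 0 (with a warning) for
    unequal means.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if method == "t":
        if a.size < 2 or b.size < 2:
            raise ValueError("t-test needs at least two values per group")
        if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            warnings.warn(
                "zero within-group variance with unequal means: p set to 0",
                stacklevel=2,
            )
            return np.inf, 0.0
        res = stats.ttest_ind(a, b, equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if method == "wilcoxon":
        if a.size < 1 or b.size < 1:
            raise ValueError("rank-sum test needs at least one value per group")
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        mw_method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=mw_method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}; use 't' or 'wilcoxon'")
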