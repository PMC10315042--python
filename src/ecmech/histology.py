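"""IHC semi-quantitative scoring, exact 2x2 tests, Ki67 labelling index,
and cross-linked collagen partitioning.

IHC sections are scored by pathologists as a percentage-positivity category
(0-4) times a staining-intensity score (0-3); the product dichotomizes
cases into low (< 4) and high (>= 4) expression.  Group-by-class counts
form a 2x2 contingency table tested with the two-sided Fisher exact test
(probability-ordering convention: the p-value sums the hypergeometric
probabilities of all same-margin tables no more probable than the observed
one).  Chi-square variants are provided as labelled alternatives.

Collagen cross-linking is quantified by partitioning total collagen
(hydroxyproline-derived) into pepsin-soluble (non-cross-linked) and the
insoluble (cross-linked) remainder: insoluble = total - soluble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "IHCRecord",
    "ContingencyTable2x2",
    "CollagenAssayRecord",
    "CollagenPartition",
    "LabellingIndexResult",
    "HIGH_SCORE_THRESHOLD",
    "DEFAULT_PCT_BINS",
    "pct_category_from_raw",
    "ihc_classify",
    "build_contingency",
    "fisher_exact_two_sided",
    "chi2_two_sided",
    "ki67_index",
    "crosslink_partition",
]

#: product score at or above which expression is classed as "high"
HIGH_SCORE_THRESHOLD = 4

#: percentage-category bin upper edges: 0: <5%, 1: 5-25%, 2: 26-50%,
#: 3: 51-75%, 4: >75% (configurable; scoring schemes vary between reports)
DEFAULT_PCT_BINS = (5.0, 25.0, 50.0, 75.0)

#: minimum tumour cells to count for a reliable Ki67 labelling index
KI67_MIN_COUNTED = {"tumour": 1000, "organoid": 300}


@dataclass(frozen=True)
class IHCRecord:
    """One case's IHC product score and low/high class."""

    case_id: str
    group: str
    pct_category: int
    intensity: int
    score: int
    label: str  # "low" | "high"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Group-by-class counts; rows = groups, columns = (low, high)."""

    a: int  # group_a, low
    b: int  # group_a, high
    c: int  # group_b, low
    d: int  # group_b, high
    group_a: str = "A"
    group_b: str = "B"

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("contingency counts must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class CollagenAssayRecord:
    """One sample's total (hydroxyproline-derived) and soluble (Sircol)
    collagen, in ug per mg tissue."""

    sample_id: str
    group: str
    total: float
    soluble: float

    def __post_init__(self):
        if not self.total > 0:
            raise ValueError(f"total collagen must be positive, got {self.total}")
        if not 0 <= self.soluble <= self.total:
            raise ValueError(
                f"soluble collagen {self.soluble} outside [0, total={self.total}]"
            )

    @property
    def insoluble(self) -> float:
        return self.total - self.soluble


@dataclass(frozen=True)
class CollagenPartition:
    """Soluble/insoluble split of a sample's total collagen."""

    total: float
    soluble: float
    insoluble: float
    insoluble_fraction: float


@dataclass(frozen=True)
class LabellingIndexResult:
    """Ki67 labelling index: percent of counted tumour cells with nuclear
    positivity."""

    positive: int
    counted: int
    index: float  # percent
    context: str
    low_count: bool


def pct_category_from_raw(pct: float, bins=DEFAULT_PCT_BINS) -> int:
    """Map a raw positive-cell percentage to its 0-4 category.

    Category 0 is strictly below the first edge; each later category is
    inclusive of its upper edge (5 -> 1, 25 -> 1, 26 -> 2, ...).
    """
    if not 0 <= pct <= 100:
        raise ValueError(f"percentage must be in [0, 100], got {pct}")
    edges = np.asarray(bins, dtype=float)
    if pct < edges[0]:
        return 0
    return int(np.searchsorted(edges[1:], pct, side="left")) + 1


def ihc_classify(
    pct_category: int, intensity: int, *, case_id: str = "", group: str = ""
) -> IHCRecord:
    """Product score and dichotomized class for one IHC section.

    Score = percentage category (0-4) x intensity (0-3); class is "high"
    iff score >= 4, else "low".
    """
    if not (0 <= pct_category <= 4 and pct_category == int(pct_category)):
        raise ValueError(f"percentage category must be an integer in 0..4, got {pct_category}")
    if not (0 <= intensity <= 3 and intensity == int(intensity)):
        raise ValueError(f"intensity score must be an integer in 0..3, got {intensity}")
    score = int(pct_category) * int(intensity)
    label = "high" if score >= HIGH_SCORE_THRESHOLD else "low"
    return IHCRecord(case_id, group, int(pct_category), int(intensity), score, label)


def build_contingency(
    records: list[IHCRecord], reference_group: str | None = None
) -> ContingencyTable2x2:
    """Tabulate classified records into a 2x2 group-by-class table.

    Exactly two groups must be present.  ``reference_group`` fixes the
    first row (defaults to first group encountered in the input).
    """
    groups: list[str] = []
    for r in records:
        if r.group not in groups:
            groups.append(r.group)
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    if reference_group is not None:
        if reference_group not in groups:
            raise ValueError(f"reference group {reference_group!r} not in data")
        groups.sort(key=lambda g: g != reference_group)
    counts = {(g, lab): 0 for g in groups for lab in ("low", "high")}
    for r in records:
        counts[(r.group, r.label)] += 1
    return ContingencyTable2x2(
        a=counts[(groups[0], "low")],
        b=counts[(groups[0], "high")],
        c=counts[(groups[1], "low")],
        d=counts[(groups[1], "high")],
        group_a=groups[0],
        group_b=groups[1],
    )


def _degenerate(table: ContingencyTable2x2) -> bool:
    arr = table.as_array()
    return bool((arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any())


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    Degenerate margins (an empty row or column) give p = 1 with a warning.
    """
    if _degenerate(table):
        warnings.warn("degenerate 2x2 margins: association is undefined, p = 1", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def chi2_two_sided(table: ContingencyTable2x2, *, correction: bool = False) -> float:
    """Chi-square test of independence (labelled alternative to Fisher).

    ``correction`` applies the Yates continuity correction.  Not the
    default test in this package: the exact test is preferred at these
    sample sizes.
    """
    if _degenerate(table):
        warnings.warn("degenerate 2x2 margins: association is undefined, p = 1", stacklevel=2)
        return 1.0
    res = stats.chi2_contingency(table.as_array(), correction=correction)
    return float(res.pvalue)


def ki67_index(positive: int, counted: int, context: str = "tumour") -> LabellingIndexResult:
    """Ki67 labelling index: 100 x positive / counted.

    Protocol guidelines call for at least 1000 counted tumour cells in
    parental-tumour sections and 300 in organoid sections; lower counts are
    flagged with a warning, not rejected.
    """
    if context not in KI67_MIN_COUNTED:
        raise ValueError(f"context must be one of {sorted(KI67_MIN_COUNTED)}, got {context!r}")
    if counted < 1:
        raise ValueError("at least one cell must be counted")
    if not 0 <= positive <= counted:
        raise ValueError(f"positive count {positive} outside [0, {counted}]")
    minimum = KI67_MIN_COUNTED[context]
    low = counted < minimum
    if low:
        warnings.warn(
            f"only {counted} cells counted; guideline for {context} is >= {minimum}",
            stacklevel=2,
        )
    return LabellingIndexResult(
        positive=int(positive),
        counted=int(counted),
        index=100.0 * positive / counted,
        context=context,
        low_count=low,
    )


def crosslink_partition(total: float, soluble: float) -> CollagenPartition:
    """Partition total collagen into soluble and insoluble (cross-linked).

    insoluble = total - soluble; the insoluble fraction insoluble/total is
    the cross-linking readout.  Conservation (soluble + insoluble = total)
    holds exactly by construction.
    """
    if not total > 0:
        raise ValueError(f"total collagen must be positive, got {total}")
    if not 0 <= soluble <= total:
        raise ValueError(f"soluble collagen {soluble} outside [0, total={total}]")
    insoluble = total - soluble
    return CollagenPartition(
        total=float(total),
        soluble=float(soluble),
        insoluble=float(insoluble),
        insoluble_fraction=float(insoluble / total),
    )
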