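"""Published summary data bundled as analysis inputs.

The IHC contingency counts below are the published low/high tallies for
four ECM-remodelling markers scored on archived benign (PA, n = 14) and
carcinoma (CXPA, n = 14) salivary tumour cohorts.  Rows are (PA low,
PA high, CXPA low, CXPA high); they are the standard worked example for
the exact-test stage of this package.
"""

from __future__ import annotations

from .histology import ContingencyTable2x2

__all__ = ["PUBLISHED_IHC_COUNTS", "published_ihc_table"]

PUBLISHED_IHC_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "COL1A1": (10, 4, 3, 11),
    "IGFBP5": (8, 6, 1, 13),
    "DCN": (10, 4, 1, 13),
    "TWIST1": (11, 3, 2, 12),
}


def published_ihc_table(marker: str) -> ContingencyTable2x2:
    """The published 2x2 low/high table for one IHC marker."""
    try:
        a, b, c, d = PUBLISHED_IHC_COUNTS[marker]
    except KeyError:
        raise KeyError(
            f"unknown marker {marker!r}; available: {sorted(PUBLISHED_IHC_COUNTS)}"
        ) from None
    return ContingencyTable2x2(a=a, b=b, c=c, d=d, group_a="PA", group_b="CXPA")
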