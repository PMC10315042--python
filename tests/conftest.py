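"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: published low/high IHC tallies (PA n=14 vs CXPA n=14) and their reported
#: two-sided exact p-values, used as desk-scale ground truth
PUBLISHED_TABLES = {
    "COL1A1": ((10, 4, 3, 11), 0.021),
    "IGFBP5": ((8, 6, 1, 13), 0.013),
    "DCN": ((10, 4, 1, 13), 0.001),
    "TWIST1": ((11, 3, 2, 12), 0.002),
}


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit enumeration, in exact rational arithmetic.

    Enumerates every 2x2 table with the observed margins and sums the
    hypergeometric probabilities of those no more probable than the
    observed table.  Independent of scipy.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return float(total)


def alignment_index_oracle(angles_deg) -> float:
    """Term-by-term AI evaluation with math.cos at full precision."""
    angles = [float(a) % 180.0 for a in angles_deg]
    med = float(np.median(angles))
    total = 0.0
    for a in angles:
        total += math.cos(math.radians(a - med)) ** 2
    return total / len(angles)


@pytest.fixture
def rng():
    return np.random.default_rng(20230701)
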