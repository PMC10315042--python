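"""IHC scoring, exact 2x2 tests, Ki67 index, and collagen partitioning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import PUBLISHED_TABLES, fisher_oracle
from ecmech.histology import (
    CollagenAssayRecord,
    ContingencyTable2x2,
    build_contingency,
    chi2_two_sided,
    crosslink_partition,
    fisher_exact_two_sided,
    ihc_classify,
    ki67_index,
    pct_category_from_raw,
)

counts = st.integers(min_value=0, max_value=25)


class TestIHCScoring:
    @pytest.mark.parametrize(
        "pct,intensity,score,label",
        [
            (4, 3, 12, "high"),
            (1, 1, 1, "low"),
            (2, 2, 4, "high"),  # dichotomization boundary: score 4 is high
            (3, 1, 3, "low"),
            (0, 3, 0, "low"),
        ],
    )
    def test_product_score_and_class(self, pct, intensity, score, label):
        rec = ihc_classify(pct, intensity)
        assert rec.score == score and rec.label == label

    @pytest.mark.parametrize("pct,intensity", [(5, 1), (-1, 1), (2, 4), (2, -1)])
    def test_out_of_range_categories_rejected(self, pct, intensity):
        with pytest.raises(ValueError):
            ihc_classify(pct, intensity)

    @pytest.mark.parametrize(
        "raw,category",
        [(0.0, 0), (4.9, 0), (5.0, 1), (25.0, 1), (26.0, 2), (50.0, 2), (51.0, 3), (75.0, 3), (76.0, 4), (100.0, 4)],
    )
    def test_raw_percentage_binning(self, raw, category):
        assert pct_category_from_raw(raw) == category


class TestContingency:
    def _cohort(self, n_low_a, n_a, n_low_b, n_b):
        recs = []
        for i in range(n_a):
            pct, inten = ((1, 1) if i < n_low_a else (4, 3))
            recs.append(ihc_classify(pct, inten, case_id=f"p{i}", group="PA"))
        for i in range(n_b):
            pct, inten = ((1, 1) if i < n_low_b else (4, 3))
            recs.append(ihc_classify(pct, inten, case_id=f"c{i}", group="CXPA"))
        return recs

    def test_published_cohort_layout(self):
        table = build_contingency(self._cohort(10, 14, 3, 14), reference_group="PA")
        assert (table.a, table.b, table.c, table.d) == (10, 4, 3, 11)
        assert (table.group_a, table.group_b) == ("PA", "CXPA")

    def test_record_order_irrelevant(self, rng):
        recs = self._cohort(8, 14, 1, 14)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        t1 = build_contingency(recs, reference_group="PA")
        t2 = build_contingency(shuffled, reference_group="PA")
        assert (t1.a, t1.b, t1.c, t1.d) == (t2.a, t2.b, t2.c, t2.d)

    def test_empty_class_still_counted(self):
        table = build_contingency(self._cohort(0, 5, 5, 5), reference_group="PA")
        assert (table.a, table.b, table.c, table.d) == (0, 5, 5, 0)

    def test_wrong_group_count_rejected(self):
        recs = self._cohort(2, 3, 1, 3)
        recs.append(ihc_classify(1, 1, case_id="x", group="other"))
        with pytest.raises(ValueError, match="exactly two groups"):
            build_contingency(recs)


class TestFisherExact:
    @pytest.mark.parametrize("marker", sorted(PUBLISHED_TABLES))
    def test_reproduces_published_pvalues(self, marker):
        (a, b, c, d), printed = PUBLISHED_TABLES[marker]
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        assert round(p, 3) == printed

    def test_symmetric_table_gives_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_degenerate_margins_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            p = fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 4))
        assert p == 1.0

    @given(counts, counts, counts, counts)
    def test_invariant_under_row_and_column_swaps(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        assert fisher_exact_two_sided(ContingencyTable2x2(c, d, a, b)) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_two_sided(ContingencyTable2x2(b, a, d, c)) == pytest.approx(p, rel=1e-9)

    @given(counts, counts, counts, counts)
    def test_agrees_with_enumeration_oracle(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-6, abs=1e-12)

    def test_chi2_alternatives_run_but_differ_from_exact(self):
        table = ContingencyTable2x2(10, 4, 1, 13)
        p_fisher = fisher_exact_two_sided(table)
        p_plain = chi2_two_sided(table)
        p_yates = chi2_two_sided(table, correction=True)
        assert 0 < p_plain < 1 and 0 < p_yates < 1
        assert p_plain != p_fisher  # approximations, not the reference test

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestKi67:
    def test_organoid_example(self):
        res = ki67_index(110, 300, "organoid")
        assert res.index == pytest.approx(36.6667, abs=1e-3)
        assert not res.low_count

    def test_zero_positive(self):
        assert ki67_index(0, 1000, "tumour").index == 0.0

    def test_low_count_warning_below_protocol_minimum(self):
        with pytest.warns(UserWarning, match="996 cells"):
            res = ki67_index(73, 996, "tumour")
        assert res.index == pytest.approx(7.3293, abs=1e-3)
        assert res.low_count

    def test_positive_exceeding_counted_rejected(self):
        with pytest.raises(ValueError):
            ki67_index(301, 300, "organoid")

    def test_unknown_context_rejected(self):
        with pytest.raises(ValueError, match="context"):
            ki67_index(10, 400, "spheroid")


class TestCrosslinkPartition:
    def test_basic_split(self):
        part = crosslink_partition(10.0, 4.0)
        assert part.insoluble == 6.0 and part.insoluble_fraction == 0.6

    def test_fully_soluble_and_fully_crosslinked(self):
        assert crosslink_partition(3.7, 3.7).insoluble == 0.0
        part = crosslink_partition(3.7, 0.0)
        assert part.insoluble == 3.7 and part.insoluble_fraction == 1.0

    @given(
        st.floats(min_value=1e-6, max_value=1e6),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_conservation_to_machine_precision(self, total, frac):
        soluble = total * frac
        part = crosslink_partition(total, soluble)
        # conserved to machine precision (subtraction then addition may
        # round by one ulp)
        assert abs(part.soluble + part.insoluble - part.total) <= 2 * np.spacing(part.total)

    @pytest.mark.parametrize("total,soluble", [(0.0, 0.0), (-1.0, 0.0), (5.0, 6.0), (5.0, -0.1)])
    def test_invalid_inputs_rejected(self, total, soluble):
        with pytest.raises(ValueError):
            crosslink_partition(total, soluble)

    def test_record_insoluble_property(self):
        rec = CollagenAssayRecord("s1", "PA", total=8.0, soluble=3.0)
        assert rec.insoluble == 5.0
        with pytest.raises(ValueError):
            CollagenAssayRecord("s2", "PA", total=2.0, soluble=3.0)
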