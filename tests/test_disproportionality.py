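"""ROR statistics: published tables, Woolf CI, properties, corrections."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.disproportionality import (
    CohortSummary,
    ContingencyTable,
    DegenerateTableError,
    build_contingency,
    pooled_comparator,
    relative_ror,
    ror,
    summarize_arm,
    z_from_confidence,
)
from faerspv.reference import comparator_summaries, exposure_summary


def _table(a, b, c, d):
    return ContingencyTable(a=a, b=b, c=c, d=d)


METHADONE = CohortSummary(substance="methadone", n_total_adr_paediatric=2297, n_event_validated=17)
BUPRENORPHINE = CohortSummary(
    substance="buprenorphine", n_total_adr_paediatric=1199, n_event_validated=15
)


class TestBuildContingency:
    def test_head_to_head_cells(self):
        t = build_contingency(METHADONE, BUPRENORPHINE)
        assert (t.a, t.b, t.c, t.d) == (17, 2280, 15, 1184)

    def test_pooled_cells(self):
        pooled = pooled_comparator(comparator_summaries())
        t = build_contingency(METHADONE, pooled)
        assert (t.a, t.b, t.c, t.d) == (17, 2280, 42, 1549)

    def test_zero_event_case(self):
        t = build_contingency(
            CohortSummary(substance="x", n_total_adr_paediatric=10, n_event_validated=0),
            CohortSummary(substance="y", n_total_adr_paediatric=10, n_event_validated=0),
        )
        assert (t.a, t.b, t.c, t.d) == (0, 10, 0, 10)

    def test_event_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            CohortSummary(substance="x", n_total_adr_paediatric=5, n_event_validated=6)


class TestPublishedAnalyses:
    """The three published 2x2 analyses, at 2-decimal display precision."""

    @pytest.mark.parametrize(
        "cells, expect_ror, expect_ci, expect_signal",
        [
            ((17, 2280, 15, 1184), 0.59, (0.29, 1.18), "not_significant"),
            ((17, 2280, 42, 1549), 0.27, (0.16, 0.48), "lower_reporting"),
            ((15, 1184, 42, 1549), 0.47, (0.26, 0.85), "lower_reporting"),
        ],
    )
    def test_ror_and_woolf_ci(self, cells, expect_ror, expect_ci, expect_signal):
        result = ror(_table(*cells))
        assert result.ror_rounded == expect_ror
        assert result.ci_rounded == expect_ci
        assert result.signal == expect_signal

    def test_symmetric_table_not_significant(self):
        result = ror(_table(10, 100, 10, 100))
        assert result.ror_rounded == 1.00
        assert result.ci_low < 1.0 < result.ci_high
        assert result.signal == "not_significant"

    def test_reverse_direction_is_reciprocal(self):
        fwd = relative_ror(METHADONE, BUPRENORPHINE)
        rev = relative_ror(BUPRENORPHINE, METHADONE)
        assert rev.ror == pytest.approx(1.0 / fwd.ror)
        assert rev.ror == pytest.approx(1.0 / 0.5886, rel=1e-3)

    def test_identical_summaries_give_exactly_one(self):
        assert relative_ror(METHADONE, METHADONE.model_copy()).ror == 1.0


class TestZeroCells:
    def test_zero_cell_errors_and_names_the_correction(self):
        with pytest.raises(DegenerateTableError, match="haldane"):
            ror(_table(0, 100, 5, 100))

    def test_haldane_correction_closed_form(self):
        # hand computation on corrected cells (0.5, 100.5, 5.5, 100.5)
        result = ror(_table(0, 100, 5, 100), correction="haldane")
        expect = (0.5 / 100.5) / (5.5 / 100.5)
        se = math.sqrt(1 / 0.5 + 1 / 100.5 + 1 / 5.5 + 1 / 100.5)
        assert result.ror == pytest.approx(expect)
        assert result.ci_low == pytest.approx(expect * math.exp(-1.96 * se))
        assert result.ci_high == pytest.approx(expect * math.exp(1.96 * se))


class TestPooledComparator:
    def test_thirteen_psychotropics_sum_to_42_of_1591(self):
        pooled = pooled_comparator(comparator_summaries())
        assert pooled.n_event_validated == 42
        assert pooled.n_total_adr_paediatric == 1591

    def test_benzodiazepine_subset_sums_to_25(self):
        from faerspv.reference import PSYCHOTROPIC_CLASS_MAP

        benzos = [
            s for s in comparator_summaries()
            if PSYCHOTROPIC_CLASS_MAP[s.substance] == "benzodiazepine"
        ]
        assert pooled_comparator(benzos).n_event_validated == 25

    def test_single_summary_is_identity(self):
        (one,) = comparator_summaries()[:1]
        pooled = pooled_comparator([one])
        assert pooled.n_total_adr_paediatric == one.n_total_adr_paediatric
        assert pooled.n_event_validated == one.n_event_validated

    def test_exposure_leakage_rejected(self):
        with pytest.raises(ValueError, match="leak|present"):
            pooled_comparator(
                comparator_summaries() + [exposure_summary("methadone")],
                exclude_substances=frozenset({"methadone"}),
            )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pooled_comparator([])


class TestInvariants:
    @given(
        a=st.integers(1, 500),
        b=st.integers(1, 5000),
        c=st.integers(1, 500),
        d=st.integers(1, 5000),
    )
    @settings(max_examples=200, deadline=None)
    def test_reciprocity_and_log_symmetry(self, a, b, c, d):
        fwd = ror(_table(a, b, c, d))
        rev = ror(_table(c, d, a, b))
        assert fwd.ror * rev.ror == pytest.approx(1.0, rel=1e-12)
        mid = 0.5 * (math.log(fwd.ci_low) + math.log(fwd.ci_high))
        assert mid == pytest.approx(math.log(fwd.ror), abs=1e-9)
        assert fwd.ci_low <= fwd.ror <= fwd.ci_high

    @given(
        a=st.integers(1, 100),
        b=st.integers(1, 1000),
        c=st.integers(1, 100),
        d=st.integers(1, 1000),
        k=st.integers(2, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_point_estimate_scale_invariant_ci_narrows(self, a, b, c, d, k):
        base = ror(_table(a, b, c, d))
        scaled = ror(_table(a * k, b * k, c, d))
        assert scaled.ror == pytest.approx(base.ror, rel=1e-12)
        assert (scaled.ci_high / scaled.ci_low) < (base.ci_high / base.ci_low)

    def test_z_from_confidence(self):
        assert z_from_confidence(0.95) == pytest.approx(1.959964, abs=1e-6)


class TestCrossCheck:
    def test_against_statsmodels_table2x2(self):
        """Independent route: statsmodels' 2x2 odds ratio and log-SE."""
        sm = pytest.importorskip("statsmodels.api")
        for cells in [(17, 2280, 15, 1184), (17, 2280, 42, 1549), (15, 1184, 42, 1549)]:
            a, b, c, d = cells
            t22 = sm.stats.Table2x2(np.array([[a, b], [c, d]]))
            ours = ror(_table(*cells), z=z_from_confidence(0.95))
            assert ours.ror == pytest.approx(t22.oddsratio)
            lo, hi = t22.oddsratio_confint(0.05)
            assert ours.ci_low == pytest.approx(lo)
            assert ours.ci_high == pytest.approx(hi)


class TestSummarizeArm:
    def test_counts_events_and_totals(self, taxonomy):
        from faerspv.model import CaseReport, DrugEntry, ReactionTerm

        def rep(cid, pts, age=(2.0, "year")):
            return CaseReport(
                case_id=cid,
                age_value=age[0],
                age_unit=age[1],
                drugs=(DrugEntry(verbatim_name="Methadone"),),
                reactions=frozenset(
                    ReactionTerm(pt=p, category=taxonomy.categorize(p)) for p in pts
                ),
            )

        reports = [
            rep("A", ["Nystagmus"]),
            rep("B", ["Somnolence"]),
            rep("C", ["Miosis"], age=(30.0, "year")),  # adult: outside denominator
        ]
        s = summarize_arm(reports, "methadone")
        assert (s.n_total_adr_paediatric, s.n_event_validated) == (2, 1)
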