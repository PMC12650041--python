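"""Report data model, normalization and round-trip serialization."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.io import FormatError, LoadAudit, load_reports, report_to_dict, write_reports
from faerspv.model import CaseReport, DrugEntry, ReactionTerm
from faerspv.substances import canonical_label, normalize_substance
from faerspv.synthetic import CohortConfig, DrugBlock, generate_cohort


def _report(case_id="C1", **kw):
    base = dict(
        case_id=case_id,
        age_value=6.0,
        age_unit="month",
        sex="F",
        drugs=(DrugEntry(verbatim_name="Methadone"),),
        reactions=frozenset({ReactionTerm(pt="Nystagmus", category="eye_disorder_general")}),
        outcomes=frozenset({"other"}),
    )
    base.update(kw)
    return CaseReport(**base)


class TestModel:
    def test_age_unit_required_when_age_present(self):
        with pytest.raises(ValueError, match="age_unit"):
            _report(age_value=2.0, age_unit=None)

    def test_age_conversion_to_years(self):
        assert _report(age_value=6, age_unit="month").age_years == pytest.approx(0.5)
        assert _report(age_value=365.25, age_unit="day").age_years == pytest.approx(1.0)

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError, match="outcome"):
            _report(outcomes=frozenset({"exploded"}))

    def test_combination_product_counts_for_constituent_exposure(self):
        entry = DrugEntry(verbatim_name="Buprenorphine/Naloxone")
        assert entry.canonical_substances == ("buprenorphine", "naloxone")
        assert entry.names_substance({"buprenorphine"})
        assert not entry.names_substance({"methadone"})


class TestNormalizeSubstance:
    @pytest.mark.parametrize(
        "verbatim, expected",
        [
            ("METHADONE HYDROCHLORIDE", ("methadone",)),
            ("valproate sodium", ("valproic acid",)),
            ("Valproic acid", ("valproic acid",)),
            ("Buprenorphine/Naloxone", ("buprenorphine", "naloxone")),
            ("  Diazepam  ", ("diazepam",)),
        ],
    )
    def test_known_forms(self, verbatim, expected):
        assert normalize_substance(verbatim) == expected

    def test_salt_synonyms_collapse_to_one_substance(self):
        assert normalize_substance("valproate sodium") == normalize_substance("Valproic acid")

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            normalize_substance("   ")

    @given(st.text(alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Zs")), min_size=1).filter(str.strip))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, name):
        once = normalize_substance(name)
        assert normalize_substance(canonical_label(name)) == once


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["jsonl", "faers_tables"])
    def test_generated_cohort_round_trips(self, tmp_path, dialect):
        cfg = CohortConfig(
            drugs=[
                DrugBlock(
                    substance="Methadone",
                    n_reports=50,
                    p_event=0.4,
                    context_mix={"in_utero": 0.7, "accidental": 0.3},
                ),
                DrugBlock(substance="Buprenorphine/Naloxone", n_reports=50, p_event=0.2),
            ],
            seed=11,
        )
        reports = generate_cohort(cfg)
        dest = tmp_path / ("reports.jsonl" if dialect == "jsonl" else "tables")
        write_reports(reports, dest, dialect)
        loaded = load_reports(dest, dialect)
        assert [report_to_dict(r) for r in loaded] == [report_to_dict(r) for r in reports]

    def test_missing_age_round_trips_as_missing_not_zero(self, tmp_path):
        r = _report(age_value=None, age_unit=None)
        for dialect, dest in (("jsonl", tmp_path / "r.jsonl"), ("faers_tables", tmp_path / "t")):
            write_reports([r], dest, dialect)
            (loaded,) = load_reports(dest, dialect)
            assert loaded.age_value is None and loaded.age_unit is None

    def test_empty_list_writes_valid_skeleton(self, tmp_path):
        dest = write_reports([], tmp_path / "empty", "faers_tables")
        assert load_reports(dest, "faers_tables") == []

    def test_dollar_delimiter_round_trips(self, tmp_path):
        reports = [_report("C1"), _report("C2", sex="M")]
        dest = tmp_path / "tables"
        write_reports(reports, dest, "faers_tables", delimiter="$")
        loaded = load_reports(dest, "faers_tables", delimiter="$")
        assert [report_to_dict(r) for r in loaded] == [report_to_dict(r) for r in reports]


class TestTablesJoin:
    def _write_raw(self, tmp_path, demo, drugs, reactions, outcomes):
        (tmp_path / "demographics.tsv").write_text(demo)
        (tmp_path / "drugs.tsv").write_text(drugs)
        (tmp_path / "reactions.tsv").write_text(reactions)
        (tmp_path / "outcomes.tsv").write_text(outcomes)

    def test_join_arity(self, tmp_path):
        self._write_raw(
            tmp_path,
            "case_id\tversion\tage_value\tage_unit\tsex\treporter\treport_year\tcountry\n"
            "C1\t0\t2\tyear\tF\tphysician\t2020\tUS\n",
            "case_id\tdrug_name\trole\nC1\tMethadone\tsuspect\nC1\tDiazepam\tconcomitant\n",
            "case_id\tpt\nC1\tNystagmus\nC1\tStrabismus\nC1\tSomnolence\n",
            "case_id\toutcome_code\nC1\tother\n",
        )
        (report,) = load_reports(tmp_path, "faers_tables")
        assert len(report.drugs) == 2
        assert len(report.reactions) == 3

    def test_dangling_rows_collected_not_dropped_silently(self, tmp_path):
        self._write_raw(
            tmp_path,
            "case_id\tversion\tage_value\tage_unit\tsex\treporter\treport_year\tcountry\n"
            "C1\t0\t\t\tF\t\t\t\n",
            "case_id\tdrug_name\trole\nC1\tMethadone\tsuspect\nGHOST\tDiazepam\tsuspect\n",
            "case_id\tpt\nC1\tMiosis\n",
            "case_id\toutcome_code\n",
        )
        audit = LoadAudit()
        reports = load_reports(tmp_path, "faers_tables", audit=audit)
        assert len(reports) == 1
        assert len(audit.rejects) == 1
        assert audit.rejects[0]["case_id"] == "GHOST"
        # join conservation: loaded drug rows + rejects == raw drug rows
        assert sum(len(r.drugs) for r in reports) + len(audit.rejects) == 2

    def test_missing_mandatory_column_names_it(self, tmp_path):
        self._write_raw(
            tmp_path,
            "case_id\tversion\tage_value\tage_unit\tsex\treporter\treport_year\tcountry\n",
            "case_id\trole\n",  # drug_name missing
            "case_id\tpt\n",
            "case_id\toutcome_code\n",
        )
        with pytest.raises(FormatError, match="drug_name"):
            load_reports(tmp_path, "faers_tables")

    def test_version_supersession_keeps_highest(self, tmp_path):
        reports = [_report("C1", version=0), _report("C1", version=2, sex="M")]
        dest = tmp_path / "r.jsonl"
        with open(dest, "w") as fh:
            for r in reports:
                fh.write(json.dumps(report_to_dict(r)) + "\n")
        audit = LoadAudit()
        (loaded,) = load_reports(dest, "jsonl", audit=audit)
        assert loaded.version == 2 and loaded.sex == "M"
        assert audit.n_version_superseded == 1


def test_table1_style_sex_tally_of_validated_methadone_cases(
    fig1_cohort, methadone_criteria
):
    """The 17 surviving methadone cases tally 6 F / 4 M / 7 unspecified."""
    from collections import Counter

    from faerspv.selection import select_cases

    survivors, _ = select_cases(fig1_cohort, methadone_criteria)
    tally = Counter(r.sex for r in survivors)
    assert tally == {"F": 6, "M": 4, "unspecified": 7}
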