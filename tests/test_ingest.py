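"""Raw-table parsing, deduplication, report filters and demographics."""

import collections

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.dates import PartialDate
from pvsignal.ingest import (
    IngestError,
    MeddraMap,
    assemble_reports,
    deduplicate_faers,
    exclude_country,
    filter_target_drug_ps,
    map_events,
    parse_faers_quarter,
    parse_jader_tables,
    remove_deleted_cases,
    summarize_demographics,
)
from pvsignal.model import (
    AdverseEvent,
    DrugEntry,
    SafetyReport,
    read_reports,
    report_from_dict,
    report_to_dict,
    write_reports,
)

TARGET = "IRINOTECAN"


def _report(rid="1", country="US", drugs=None, events=None, **kw):
    return SafetyReport(
        report_id=rid,
        case_id=rid,
        source_db="FAERS",
        country=country,
        drugs=drugs if drugs is not None else [DrugEntry(TARGET, "PS")],
        events=events if events is not None else [AdverseEvent("Diarrhoea")],
        **kw,
    )


# ---------------------------------------------------------------------------
# Parsers


class TestFaersParsing:
    def test_row_count_and_field_parse(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text(
            "PRIMARYID$CASEID$FDA_DT$SEX\n101$1$20240315$M\n201$2$20230101$F\n"
        )
        (tmp_path / "DRUG.txt").write_text(
            "PRIMARYID$CASEID$DRUG_SEQ$ROLE_COD$DRUGNAME\n101$1$1$SS$OXALIPLATIN\n"
        )
        (tmp_path / "REAC.txt").write_text("PRIMARYID$CASEID$PT\n101$1$Nausea\n")
        tables = parse_faers_quarter(
            {"demo": tmp_path / "DEMO.txt", "drug": tmp_path / "DRUG.txt",
             "reac": tmp_path / "REAC.txt"}
        )
        assert len(tables.demo) == 2  # header + 2 rows -> 2 records
        reports = assemble_reports(tables)
        assert reports[0].receipt_date == PartialDate(2024, 3, 15)
        # field-by-field manual parse of the DRUG row
        assert reports[0].drugs == [DrugEntry("OXALIPLATIN", "SS")]

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text("PRIMARYID$FDA_DT\n101$20240315\n")
        (tmp_path / "DRUG.txt").write_text("PRIMARYID$CASEID$ROLE_COD$DRUGNAME\n")
        (tmp_path / "REAC.txt").write_text("PRIMARYID$CASEID$PT\n")
        with pytest.raises(IngestError, match="DEMO.txt.*CASEID"):
            parse_faers_quarter(
                {"demo": tmp_path / "DEMO.txt", "drug": tmp_path / "DRUG.txt",
                 "reac": tmp_path / "REAC.txt"}
            )

    def test_malformed_rows_counted_not_fatal(self, tmp_path):
        (tmp_path / "DEMO.txt").write_text(
            "PRIMARYID$CASEID$FDA_DT\n101$1$20240315\n201$2$20230101$EXTRA$EXTRA\n"
        )
        (tmp_path / "DRUG.txt").write_text("PRIMARYID$CASEID$ROLE_COD$DRUGNAME\n")
        (tmp_path / "REAC.txt").write_text("PRIMARYID$CASEID$PT\n")
        tables = parse_faers_quarter(
            {"demo": tmp_path / "DEMO.txt", "drug": tmp_path / "DRUG.txt",
             "reac": tmp_path / "REAC.txt"}
        )
        assert len(tables.demo) == 1
        assert tables.malformed["demo"] == 1


class TestJaderParsing:
    def _write(self, tmp_path, encoding="cp932"):
        (tmp_path / "demo.csv").write_text(
            "識別番号,報告回数,性別,年齢,体重\n1,1,男性,60歳代,50kg台\n2,1,女性,70歳代,\n",
            encoding=encoding,
        )
        (tmp_path / "drug.csv").write_text(
            "識別番号,医薬品の関与,医薬品（一般名）,投与開始日,投与終了日\n"
            "1,被疑薬,イリノテカン,20200105,\n2,併用薬,オキサリプラチン,,\n",
            encoding=encoding,
        )
        (tmp_path / "reac.csv").write_text(
            "識別番号,有害事象,発現日,転帰\n1,下痢,2020,死亡\n2,悪心,20200210,回復\n",
            encoding=encoding,
        )
        return {k: tmp_path / f"{k}.csv" for k in ("demo", "drug", "reac")}

    def test_two_row_demo_and_role_mapping(self, tmp_path):
        tables = parse_jader_tables(self._write(tmp_path))
        assert len(tables.demo) == 2
        reports = assemble_reports(tables)
        assert reports[0].drugs[0].role == "PS"  # 被疑薬 -> primary suspect
        assert reports[0].sex == "M" and reports[1].sex == "F"
        assert reports[0].age_years == 60 and reports[0].weight_kg == 50

    def test_year_only_event_date_keeps_year_precision(self, tmp_path):
        tables = parse_jader_tables(self._write(tmp_path))
        reports = assemble_reports(tables)
        ev = reports[0].events[0]
        assert ev.event_date == PartialDate(2020)
        assert ev.event_date.precision.value == "year"

    def test_undecodable_bytes_raise_with_offset(self, tmp_path):
        paths = self._write(tmp_path)
        # 0x81 followed by a space is an invalid cp932 sequence
        (tmp_path / "demo.csv").write_bytes(b"\x81 header\n1\n")
        with pytest.raises(IngestError, match="offset"):
            parse_jader_tables(paths, encoding="cp932")


# ---------------------------------------------------------------------------
# Deduplication


def _demo_frame(rows):
    return pd.DataFrame(rows, columns=["PRIMARYID", "CASEID", "FDA_DT"])


class TestDeduplication:
    def test_most_recent_receipt_date_wins(self):
        demo = _demo_frame([("10", "1", "20200101"), ("9", "1", "20210101")])
        kept = deduplicate_faers(demo)
        assert list(kept["PRIMARYID"]) == ["9"]

    def test_date_tie_broken_by_higher_primaryid(self):
        demo = _demo_frame([("10", "1", "20200101"), ("11", "1", "20200101")])
        kept = deduplicate_faers(demo)
        assert list(kept["PRIMARYID"]) == ["11"]

    def test_distinct_cases_pass_through(self):
        demo = _demo_frame([("1", "1", "20200101"), ("2", "2", "20200102")])
        assert len(deduplicate_faers(demo)) == 2

    def test_missing_receipt_date_sorts_lowest(self):
        demo = _demo_frame([("99", "1", ""), ("5", "1", "19900101")])
        assert list(deduplicate_faers(demo)["PRIMARYID"]) == ["5"]

    def test_non_numeric_primaryids_compare_lexicographically(self):
        demo = _demo_frame([("A10", "1", "20200101"), ("A9", "1", "20200101")])
        assert list(deduplicate_faers(demo)["PRIMARYID"]) == ["A9"]

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(1, 500),
                st.integers(1, 8),
                st.sampled_from(["20200101", "20210101", "20220101", ""]),
            ),
            min_size=1,
            max_size=40,
        )
    )
    def test_idempotent_and_one_row_per_case(self, rows):
        demo = _demo_frame([(str(p), str(c), d) for p, c, d in rows])
        once = deduplicate_faers(demo)
        assert len(once) == demo["CASEID"].nunique()
        twice = deduplicate_faers(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )


# ---------------------------------------------------------------------------
# Report-level filters


class TestFilters:
    def test_deleted_case_removal_counts(self):
        reports = [_report(rid=str(i)) for i in range(1, 6)]
        kept, dropped = remove_deleted_cases(reports, {"2", "4"})
        assert len(kept) == 3 and dropped == 2
        kept, dropped = remove_deleted_cases(reports, set())
        assert len(kept) == 5 and dropped == 0
        kept, dropped = remove_deleted_cases(reports, {"99"})
        assert len(kept) == 5 and dropped == 0

    def test_primary_suspect_lexicon_match(self):
        lexicon = ["IRINOTECAN", "IRINOTECAN HCL", "IRINOTECAN HYDROCHLORIDE"]
        retained = _report(drugs=[DrugEntry("Irinotecan  Hydrochloride", "PS")])
        concomitant = _report(drugs=[DrugEntry("IRINOTECAN", "C"),
                                     DrugEntry("OXALIPLATIN", "PS")])
        unrelated = _report(drugs=[DrugEntry("CETUXIMAB", "PS")])
        kept, dropped = filter_target_drug_ps([retained, concomitant, unrelated], lexicon)
        assert kept == [retained] and dropped == 2

    def test_no_substring_matching(self):
        combo = _report(drugs=[DrugEntry("IRINOTECAN/FLUOROURACIL KIT", "PS")])
        kept, _ = filter_target_drug_ps([combo], ["IRINOTECAN"])
        assert kept == []

    def test_empty_lexicon_is_hard_error(self):
        with pytest.raises(IngestError):
            filter_target_drug_ps([_report()], [])

    def test_country_exclusion_keeps_unknown(self):
        reports = [_report(rid="1", country="US"), _report(rid="2", country="JP"),
                   _report(rid="3", country=""), _report(rid="4", country="FR")]
        kept, dropped = exclude_country(reports, "JP")
        assert dropped == 1
        assert {r.report_id for r in kept} == {"1", "3", "4"}
        kept, dropped = exclude_country(reports, "XX")
        assert dropped == 0 and len(kept) == 4

    def test_filters_commute_in_count(self):
        reports = [
            _report(rid="1", country="JP"),
            _report(rid="2", country="US"),
            _report(rid="3", country="JP", drugs=[DrugEntry("CETUXIMAB", "PS")]),
            _report(rid="4", country="US", drugs=[DrugEntry(TARGET, "C")]),
        ]
        a, _ = exclude_country(filter_target_drug_ps(reports, [TARGET])[0], "JP")
        b, _ = filter_target_drug_ps(exclude_country(reports, "JP")[0], [TARGET])
        assert len(a) == len(b)


# ---------------------------------------------------------------------------
# SOC mapping and demographics


class TestMapping:
    MAP = MeddraMap({"diarrhoea": "Gastrointestinal disorders"})

    def test_mapped_and_unmapped_and_casefold(self):
        reports = [
            _report(events=[AdverseEvent("Diarrhoea"), AdverseEvent("Hiccups")]),
            _report(rid="2", events=[AdverseEvent("diarrhoea")]),
        ]
        mapped, unmapped = map_events(reports, self.MAP)
        assert mapped[0].events[0].soc == "Gastrointestinal disorders"
        assert mapped[0].events[1].soc == "UNMAPPED"
        assert mapped[1].events[0].soc == "Gastrointestinal disorders"
        assert unmapped == collections.Counter({"hiccups": 1})


class TestDemographics:
    def test_sex_share(self):
        reports = [_report(rid=str(i), sex="M" if i < 6 else "F") for i in range(10)]
        tables = summarize_demographics(reports)
        male = tables["sex"].set_index("category").loc["M"]
        assert male["n"] == 6 and male["percent"] == 60.0

    def test_all_missing_yields_unknown_rows(self):
        reports = [_report(rid=str(i), sex="unknown") for i in range(3)]
        tables = summarize_demographics(reports)
        assert tables["sex"].iloc[0]["percent"] == 100.0
        assert tables["age"].set_index("category").loc["unknown", "percent"] == 100.0

    def test_outcome_denominator_conventions(self):
        reports = [
            _report(rid="1", outcomes=["DE", "HO"]),
            _report(rid="2", outcomes=["HO"]),
            _report(rid="3", outcomes=[]),
        ]
        by_reports = summarize_demographics(reports, outcome_denominator="reports")
        by_entries = summarize_demographics(reports, outcome_denominator="entries")
        de_reports = by_reports["outcome"].set_index("category").loc["DE", "percent"]
        de_entries = by_entries["outcome"].set_index("category").loc["DE", "percent"]
        assert de_reports == pytest.approx(33.3)
        assert de_entries == pytest.approx(33.3)
        ho_reports = by_reports["outcome"].set_index("category").loc["HO", "percent"]
        assert ho_reports == pytest.approx(66.7)


# ---------------------------------------------------------------------------
# Interchange round trip


def test_jsonl_round_trip_field_for_field(tmp_path, mini_cleaned):
    target, _, _ = mini_cleaned
    path = tmp_path / "reports.jsonl"
    write_reports(target, path)
    back = list(read_reports(path))
    assert [report_to_dict(r) for r in back] == [report_to_dict(r) for r in target]


def test_report_dict_round_trip(planted_cleaned):
    target, _, _ = planted_cleaned
    for r in target[:25]:
        assert report_to_dict(report_from_dict(report_to_dict(r))) == report_to_dict(r)
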