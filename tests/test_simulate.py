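"""Synthetic-report generator: determinism, planted truth, fixture branches."""

import collections

import pandas as pd
import pytest

from pvsignal.contingency import build_tables_from_reports, count_events
from pvsignal.ingest import clean_reports, parse_faers_quarter, parse_jader_tables
from pvsignal.model import normalize_term
from pvsignal.simulate import PlantedSignal, SimConfig, fixture_small, simulate
from pvsignal.tto import tto_records

from conftest import TARGET, meddra_from_config


def _cfg(**kw):
    base = dict(n_reports=1500, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_identical_seed_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            res = simulate(_cfg())
            res.write_faers(tmp_path / sub)
            res.write_jader(tmp_path / sub / "jader")
        for f in (tmp_path / "a").rglob("*"):
            if f.is_file():
                other = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert f.read_bytes() == other.read_bytes(), f.name

    def test_different_seed_differs(self):
        a = simulate(_cfg(seed=5)).faers.demo
        b = simulate(_cfg(seed=6)).faers.demo
        assert not a.equals(b)


class TestConfig:
    def test_zero_duplicate_rate_gives_unique_primaryids(self):
        res = simulate(_cfg(duplicate_rate=0.0))
        assert res.faers.demo["PRIMARYID"].is_unique
        assert res.faers.demo["CASEID"].is_unique

    def test_infeasible_lambda_rejected_before_writing(self):
        with pytest.raises(ValueError, match="probability above 1"):
            simulate(_cfg(planted_signals=[PlantedSignal(TARGET, "PT_001", 1e6)]))
        with pytest.raises(ValueError):
            simulate(_cfg(planted_signals=[PlantedSignal(TARGET, "PT_001", -1.0)]))

    def test_country_mix_must_normalize(self):
        with pytest.raises(ValueError, match="country mix"):
            SimConfig(n_reports=10, seed=0, country_mix={"US": 0.5}).validate()


class TestPlantedTruth:
    def test_expected_counts_match_empirical_within_3sd(self):
        cfg = _cfg(
            n_reports=6000,
            duplicate_rate=0.0,
            deleted_rate=0.0,
            planted_signals=[
                PlantedSignal(TARGET, "PT_010", 10.0),
                PlantedSignal(TARGET, "PT_050", 4.0),
            ],
        )
        res = simulate(cfg)
        # empirical a for the target drug straight from the raw row tables
        target_pids = set(
            res.faers.drug.query("ROLE_COD == 'PS' and DRUGNAME == @TARGET")["PRIMARYID"]
        )
        reac = res.faers.reac[res.faers.reac["PRIMARYID"].isin(target_pids)]
        counts = reac.groupby("PT")["PRIMARYID"].nunique()
        for _, row in res.truth.pair_truth.iterrows():
            expected = row["expected_a"]
            observed = counts.get(row["pt"], 0)
            sd = max(expected**0.5, 1.0)
            assert abs(observed - expected) <= 3 * sd, (row["pt"], observed, expected)

    def test_round_trip_recovers_a_counts_exactly(self):
        """generate → ingest → contingency reproduces raw-file pair counts."""
        cfg = _cfg(duplicate_rate=0.0, deleted_rate=0.0,
                   planted_signals=[PlantedSignal(TARGET, "PT_010", 10.0)])
        res = simulate(cfg)
        target, background, _ = clean_reports(
            res.faers, [TARGET], meddra_from_config(cfg)
        )
        tables = {t.term: t.a for t in build_tables_from_reports(target, background)}
        target_pids = set(
            res.faers.drug.query("ROLE_COD == 'PS' and DRUGNAME == @TARGET")["PRIMARYID"]
        )
        reac = res.faers.reac[res.faers.reac["PRIMARYID"].isin(target_pids)]
        oracle = reac.groupby(reac["PT"].map(normalize_term))["PRIMARYID"].nunique()
        assert tables == oracle.to_dict()

    def test_true_tto_matches_computed_on_clean_dates(self):
        cfg = _cfg(duplicate_rate=0.0, deleted_rate=0.0,
                   date_missing_rate=0.0, date_imprecise_rate=0.0,
                   negative_tto_rate=0.0)
        res = simulate(cfg)
        target, _, _ = clean_reports(res.faers, [TARGET], meddra_from_config(cfg))
        truth = res.truth.report_truth.set_index("primaryid")["true_tto"]
        recs = tto_records(target, [TARGET])
        assert recs and all(r.status == "included" for r in recs)
        for r in recs:
            assert r.tto_days == truth.loc[r.report_id]


class TestDialectConsistency:
    def test_jader_mirror_has_same_target_counts(self, tmp_path):
        cfg = _cfg(duplicate_rate=0.0, deleted_rate=0.0)
        res = simulate(cfg)
        res.write_faers(tmp_path / "faers")
        res.write_jader(tmp_path / "jader")
        meddra = meddra_from_config(cfg)
        ft = parse_faers_quarter(
            {k: tmp_path / "faers" / f"{k.upper()}.txt"
             for k in ("demo", "drug", "reac", "ther", "outc", "indi")}
        )
        jt = parse_jader_tables(
            {k: tmp_path / "jader" / f"{k}.csv" for k in ("demo", "drug", "reac", "hist")}
        )
        ta, _, _ = clean_reports(ft, [TARGET], meddra)
        tb, _, _ = clean_reports(jt, [TARGET], meddra)
        assert count_events(ta) == count_events(tb)


class TestFixtureSmall:
    def test_constructed_branches(self, mini_cleaned):
        target, background, ledger = mini_cleaned
        # duplicate pair: exactly one survivor, the later-dated version
        survivors = [r for r in target if r.case_id == "2"]
        assert len(survivors) == 1 and survivors[0].report_id == "202"
        # deleted case 3 and Japan case 4 are gone
        assert not any(r.case_id in {"3", "4"} for r in background)
        assert ledger["dropped_deleted_case"] == 1
        assert ledger["dropped_excluded_country"] == 1
        # concomitant-only and secondary-suspect mentions dropped from target
        assert not any(r.case_id in {"5", "6", "9"} for r in target)
        assert {r.case_id for r in target} == {"1", "2", "7", "8"} | {
            str(i) for i in range(10, 21)
        }

    def test_exactly_one_negative_tto(self, mini_cleaned):
        target, _, _ = mini_cleaned
        recs = tto_records(target, [TARGET])
        status = collections.Counter(r.status for r in recs)
        assert status["excluded_negative"] == 1
        assert status["excluded_imprecise"] == 1  # the month-precision start

    def test_fixture_is_deterministic(self):
        a = fixture_small()[0].demo
        b = fixture_small()[0].demo
        pd.testing.assert_frame_equal(a, b)
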