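import pytest

from faerspv import cleaning
from faerspv.cleaning import (
    DedupKey,
    age_to_years,
    clean_cases,
    dedup_cross_caseid,
    drop_deleted,
    filter_valid_age,
    keep_latest_per_caseid,
)
from faerspv.faers_io import CaseReport, DrugRecord

from conftest import assemble


def make_case(
    caseid="1",
    primaryid=None,
    caseversion=1,
    fda_dt="20200101",
    event_dt="20191201",
    age="65",
    age_cod="YR",
    country="US",
    pts=("Toy event A",),
    drugnames=("IBRANCE",),
):
    return CaseReport(
        caseid=caseid,
        primaryid=primaryid or f"{caseid}{caseversion}",
        caseversion=caseversion,
        fda_dt=fda_dt,
        event_dt=event_dt,
        age=age,
        age_cod=age_cod,
        sex="F",
        occp_cod="MD",
        reporter_country=country,
        pts=set(pts),
        drugs=[
            DrugRecord(primaryid=f"{caseid}{caseversion}", drug_seq=str(i + 1),
                       role_cod="PS", drugname=name)
            for i, name in enumerate(drugnames)
        ],
    )


class TestAgeConversion:
    # unit-conversion oracle table: value, code -> years
    @pytest.mark.parametrize(
        "age, cod, years",
        [
            ("7", "DEC", 70.0),
            ("65", "YR", 65.0),
            ("6", "MON", 0.5),
            ("52.143", "WK", 1.0),
            ("730.5", "DY", 2.0),
            ("8766", "HR", 1.0),
            ("40", "", 40.0),  # missing unit treated as years
        ],
    )
    def test_conversion_table(self, age, cod, years):
        assert age_to_years(age, cod) == pytest.approx(years)

    @pytest.mark.parametrize(
        "age, cod",
        [
            ("", ""),  # unclear age
            ("abc", "YR"),
            ("65", "XX"),  # unknown unit code
            ("999", "YR"),  # above plausibility bound
            ("-5", "YR"),
            ("13", "DEC"),  # 130 years
        ],
    )
    def test_unclear_or_implausible_is_none(self, age, cod):
        assert age_to_years(age, cod) is None


class TestDropDeleted:
    def test_two_of_ten_removed(self):
        cases = [make_case(caseid=str(i)) for i in range(10)]
        kept = drop_deleted(cases, {"3", "7"})
        assert len(kept) == 8
        assert all(c.caseid not in {"3", "7"} for c in kept)

    def test_empty_deleted_list_is_identity(self):
        cases = [make_case(caseid=str(i)) for i in range(5)]
        assert drop_deleted(cases, set()) == cases

    def test_planted_deletions_exactly_removed(self, sim_corpus, loaded_cases):
        cases, deleted = loaded_cases
        kept = drop_deleted(list(cases), deleted)
        removed_caseids = {c.caseid for c in cases} - {c.caseid for c in kept}
        assert removed_caseids == sim_corpus.ledger.deleted_caseids


class TestKeepLatest:
    def test_most_recent_fda_date_retained(self):
        v1 = make_case(caseid="X", caseversion=1, fda_dt="20160101")
        v2 = make_case(caseid="X", caseversion=2, fda_dt="20170101")
        (kept,) = keep_latest_per_caseid([v1, v2])
        assert kept.fda_dt == "20170101"

    def test_caseversion_breaks_same_day_tie(self):
        v1 = make_case(caseid="X", caseversion=1, fda_dt="20170101")
        v2 = make_case(caseid="X", caseversion=2, fda_dt="20170101")
        (kept,) = keep_latest_per_caseid([v2, v1])
        assert kept.caseversion == 2

    def test_single_version_corpus_is_identity(self):
        cases = [make_case(caseid=str(i)) for i in range(4)]
        assert keep_latest_per_caseid(cases) == cases

    def test_output_caseids_unique(self, loaded_cases):
        cases, deleted = loaded_cases
        kept = keep_latest_per_caseid(drop_deleted(list(cases), deleted))
        caseids = [c.caseid for c in kept]
        assert len(caseids) == len(set(caseids))


class TestCrossCaseidDedup:
    def test_identical_reports_different_caseids_collapse(self):
        a = make_case(caseid="1", fda_dt="20200101")
        b = make_case(caseid="2", fda_dt="20200301")
        kept = dedup_cross_caseid([a, b])
        assert len(kept) == 1
        assert kept[0].caseid == "2"  # most recent retained

    def test_one_extra_pt_keeps_both(self):
        a = make_case(caseid="1")
        b = make_case(caseid="2", pts=("Toy event A", "Toy event B"))
        assert len(dedup_cross_caseid([a, b])) == 2

    def test_missing_fields_match_missing(self):
        a = make_case(caseid="1", age="", age_cod="", event_dt="", fda_dt="20200101")
        b = make_case(caseid="2", age="", age_cod="", event_dt="", fda_dt="20200102")
        assert len(dedup_cross_caseid([a, b])) == 1

    def test_planted_clusters_each_lose_one(self, sim_corpus, loaded_cases):
        cases, deleted = loaded_cases
        ledger = sim_corpus.ledger
        stage = keep_latest_per_caseid(drop_deleted(list(cases), deleted))
        kept = dedup_cross_caseid(stage)
        assert len(stage) - len(kept) == len(ledger.clusters)
        kept_ids = {c.caseid for c in kept}
        for original, clone in ledger.clusters:
            if original not in ledger.deleted_caseids:
                assert clone in kept_ids and original not in kept_ids

    def test_key_equality_requires_equal_content(self):
        a = make_case(caseid="1", age="65", age_cod="YR")
        b = make_case(caseid="2", age="6.5", age_cod="DEC")
        # 65 years either way: identical converted age participates in the key
        assert DedupKey.from_case(a) == DedupKey.from_case(b)


class TestFilterValidAge:
    def test_valid_age_populated(self):
        (kept,) = filter_valid_age([make_case(age="65", age_cod="YR")])
        assert kept.age_years == 65.0

    def test_unclear_age_excluded(self):
        assert filter_valid_age([make_case(age="", age_cod="")]) == []

    def test_decade_units(self):
        (kept,) = filter_valid_age([make_case(age="7", age_cod="DEC")])
        assert kept.age_years == 70.0


class TestCascade:
    def test_manifest_matches_generator_ledger(self, sim_corpus, cleaned_cases):
        cleaned, manifest = cleaned_cases
        expected = sim_corpus.ledger.expected
        assert manifest["raw"] == expected["raw"]
        assert manifest["deleted_removed"] == expected["deleted_removed"]
        assert manifest["version_removed"] == expected["version_removed"]
        assert manifest["crossdup_removed"] == expected["crossdup_removed"]
        assert manifest["age_removed"] == expected["age_removed"]
        assert {c.caseid for c in cleaned} == expected["final_caseids"]

    def test_idempotent(self, cleaned_cases):
        cleaned, _ = cleaned_cases
        again, manifest = clean_cases(list(cleaned), set())
        assert again == cleaned
        assert manifest["deleted_removed"] == 0
        assert manifest["version_removed"] == 0
        assert manifest["crossdup_removed"] == 0
        assert manifest["age_removed"] == 0

    def test_monotone_and_counts_sum(self, cleaned_cases):
        _, m = cleaned_cases
        assert m["raw"] >= m["after_deleted"] >= m["after_latest"] >= m["after_crossdup"] >= m["after_age"]
        assert m["raw"] - m["deleted_removed"] == m["after_deleted"]
        assert m["after_deleted"] - m["version_removed"] == m["after_latest"]
        assert m["after_latest"] - m["crossdup_removed"] == m["after_crossdup"]
        assert m["after_crossdup"] - m["age_removed"] == m["after_age"]

    def test_output_keys_unique(self, cleaned_cases):
        cleaned, _ = cleaned_cases
        keys = [DedupKey.from_case(c) for c in cleaned]
        assert len(keys) == len(set(keys))

    def test_dup_cluster_fixture_removes_two(self, fixture_suite):
        cases = assemble(fixture_suite["dup_cluster_3"])
        cleaned, manifest = clean_cases(cases, set())
        assert len(cases) == 3 and len(cleaned) == 1
        assert manifest["crossdup_removed"] == 2
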