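"""Report store: readers, deduplication, malignancy filter, class assignment."""

import textwrap
from datetime import date

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vegfpv.report_store import (
    DEFAULT_MALIGNANCY_TERMS,
    CaseReport,
    DrugCatalog,
    PTCatalog,
    ReportSet,
    assign_class,
    deduplicate,
    filter_malignancy,
    normalize_drug_name,
    read_faers_ascii,
    read_simple_csv,
    split_reactions,
    write_simple_csv,
)
from vegfpv.synthetic import FaersSimConfig, simulate_reports


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("BEVACIZUMAB", "bevacizumab"),
            ("  Sunitinib  ", "sunitinib"),
            ("Avastin (bevacizumab)", "avastin"),
            ("bevacizumab (Avastin)", "bevacizumab"),
        ],
    )
    def test_drug_name(self, raw, expected):
        assert normalize_drug_name(raw) == expected

    def test_reaction_split(self):
        assert split_reactions("Hypertension;Blood pressure increased") == {
            "Hypertension",
            "Blood pressure increased",
        }


class TestCaseReport:
    def test_empty_reactions_rejected(self, make_report):
        with pytest.raises(ValueError, match="reactions"):
            make_report(0, reactions=frozenset())

    def test_duplicate_ids_rejected(self, make_report):
        with pytest.raises(ValueError, match="report_id"):
            ReportSet.from_reports([make_report(0), make_report(0)])


class TestSimpleCsv:
    def test_round_trip_identity(self, small_reports, tmp_path):
        path = tmp_path / "reports.csv"
        write_simple_csv(small_reports, path)
        again = read_simple_csv(path)
        assert again == small_reports

    def test_missing_column_named(self, small_reports, tmp_path):
        path = tmp_path / "broken.csv"
        write_simple_csv(small_reports, path)
        frame = pd.read_csv(path).drop(columns=["indication"])
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="indication"):
            read_simple_csv(path)

    def test_duplicate_report_id_rejected(self, small_reports, tmp_path):
        path = tmp_path / "dup.csv"
        frame = small_reports.frame.copy()
        frame.loc[1, "report_id"] = frame.loc[0, "report_id"]
        with pytest.raises(ValueError, match="duplicate report_id"):
            ReportSet(frame)


class TestFaersAscii:
    def _write_tables(self, tmp_path, demo_rows, drug_rows, reac_rows):
        paths = {}
        tables = {
            "DEMO": ("primaryid$sex$age$age_cod$occr_country$event_dt", demo_rows),
            "DRUG": ("primaryid$drug_seq$role_cod$drugname", drug_rows),
            "REAC": ("primaryid$pt", reac_rows),
        }
        for name, (header, rows) in tables.items():
            p = tmp_path / f"{name}.txt"
            p.write_text("\n".join([header, *rows]) + "\n")
            paths[name] = p
        return paths

    def test_identity_ingestion(self, tmp_path):
        paths = self._write_tables(
            tmp_path,
            ["1$F$61$YR$US$20200301", "2$M$55$YR$JP$20210401", "3$F$70$YR$FR$20190501"],
            ["1$1$PS$SUNITINIB", "2$1$PS$BEVACIZUMAB", "3$1$SS$SORAFENIB"],
            ["1$Hypertension", "2$Hypertension", "2$Nausea", "3$Fatigue"],
        )
        rs = read_faers_ascii(paths)
        assert len(rs) == 3
        reports = {r.report_id: r for r in rs.reports}
        assert reports["2-1"].reactions == {"Hypertension", "Nausea"}
        assert reports["1-1"].drug_role == "primary_suspect"
        assert reports["3-1"].drug_role == "other"

    def test_unparseable_date_kept_absent(self, tmp_path):
        paths = self._write_tables(
            tmp_path,
            ["1$F$61$YR$US$20200301", "2$M$55$YR$JP$NOTADATE"],
            ["1$1$PS$SUNITINIB", "2$1$PS$SUNITINIB"],
            ["1$Hypertension", "2$Hypertension"],
        )
        rs = read_faers_ascii(paths)
        dates = {r.report_id: r.event_date for r in rs.reports}
        assert dates["1-1"] == date(2020, 3, 1)
        assert dates["2-1"] is None

    def test_empty_reac_join_dropped(self, tmp_path):
        paths = self._write_tables(
            tmp_path,
            ["1$F$61$YR$US$20200301", "2$M$55$YR$JP$20210401"],
            ["1$1$PS$SUNITINIB", "2$1$PS$SUNITINIB"],
            ["1$Hypertension"],
        )
        rs = read_faers_ascii(paths)
        assert [r.report_id for r in rs.reports] == ["1-1"]

    def test_missing_demo_is_hard_error(self, tmp_path):
        with pytest.raises(ValueError, match="DEMO"):
            read_faers_ascii({"DRUG": tmp_path / "missing.txt"})


class TestDeduplicate:
    def test_exact_duplicates_collapse(self, make_report):
        rs = ReportSet.from_reports([make_report(0), make_report(1)])
        assert len(deduplicate(rs)) == 1

    def test_key_mismatch_retains_both(self, make_report):
        rs = ReportSet.from_reports([make_report(0, age=45.0), make_report(1, age=46.0)])
        assert len(deduplicate(rs)) == 2

    def test_first_occurrence_kept(self, make_report):
        rs = ReportSet.from_reports([make_report(0), make_report(1)])
        out = deduplicate(rs)
        assert [r.report_id for r in out.reports] == ["R000"]

    def test_planted_duplicates_removed_exactly(self):
        cfg = FaersSimConfig(n_reports=100, seed=5, duplicate_rate=0.2)
        rs, truth = simulate_reports(cfg)
        assert len(rs) == 100 + truth["n_duplicates"]
        assert len(deduplicate(rs)) == 100

    def test_idempotent(self, small_reports):
        once = deduplicate(small_reports)
        twice = deduplicate(once)
        assert once == twice

    def test_never_increases_and_identity_without_shared_keys(self, small_reports):
        out = deduplicate(small_reports)
        assert len(out) <= len(small_reports)
        assert out == small_reports  # fixture has no duplicate keys


class TestFilterMalignancy:
    def test_carcinoma_kept(self, make_report):
        rs = ReportSet.from_reports([make_report(0, indication="Hepatocellular carcinoma")])
        assert len(filter_malignancy(rs, ["carcinoma"])) == 1

    def test_non_malignant_dropped(self, make_report):
        rs = ReportSet.from_reports([make_report(0, indication="Macular degeneration")])
        assert len(filter_malignancy(rs, list(DEFAULT_MALIGNANCY_TERMS))) == 0

    def test_blank_indication_dropped(self, make_report):
        rs = ReportSet.from_reports([make_report(0, indication="")])
        assert len(filter_malignancy(rs)) == 0

    def test_empty_terms_error(self, small_reports):
        with pytest.raises(ValueError):
            filter_malignancy(small_reports, [])

    def test_planted_fraction_recovered(self):
        cfg = FaersSimConfig(n_reports=2000, seed=7, malignant_fraction=0.6)
        rs, truth = simulate_reports(cfg)
        kept = filter_malignancy(rs)
        assert len(kept) == truth["n_malignant"]

    @given(rnd=st.randoms(use_true_random=False))
    def test_order_independent(self, small_reports, rnd):
        order = list(range(len(small_reports)))
        rnd.shuffle(order)
        shuffled = ReportSet(small_reports.frame.iloc[order])
        kept_a = {r.report_id for r in filter_malignancy(small_reports).reports}
        kept_b = {r.report_id for r in filter_malignancy(shuffled).reports}
        assert kept_a == kept_b


class TestAssignClass:
    @pytest.mark.parametrize(
        "drug,expected",
        [("bevacizumab", "VEGFi"), ("sunitinib", "VEGFRi"), ("aspirin", "other")],
    )
    def test_catalog_classes(self, drug, expected):
        assert DrugCatalog.default().classify(drug) == expected

    def test_annotation_and_primary_screen(self, small_reports):
        out = assign_class(small_reports)
        assert set(out.frame["drug_class"]) <= {"VEGFi", "VEGFRi", "other"}
        frame = small_reports.frame.copy()
        frame.loc[0, "drug_role"] = "other"
        screened = assign_class(ReportSet(frame), primary_suspect_only=True)
        assert len(screened) == len(small_reports) - 1


class TestPTCatalog:
    def test_subset_invariant_enforced(self):
        with pytest.raises(ValueError):
            PTCatalog(
                bp_related=frozenset({"Hypertension"}),
                hypertension_directly_related=frozenset({"Hypertension", "Other"}),
            )

    def test_default_structure(self):
        cat = PTCatalog.default()
        assert cat.hypertension_directly_related <= cat.bp_related
        assert len(cat.bp_related) == 18
        assert len(cat.hypertension_directly_related) == 11
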