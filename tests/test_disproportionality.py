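"""Disproportionality: contingency cells, ROR/CI, IC/IC025, signal rule."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vegfpv.disproportionality import (
    ContingencyTable,
    build_contingency,
    evaluate_pair,
    flag_signal,
    ic_with_ic025,
    per_cancer_ror,
    ror_with_ci,
    signal_table,
)
from vegfpv.report_store import ReportSet, deduplicate, filter_malignancy
from vegfpv.synthetic import DEFAULT_PT_GROUPS, FaersSimConfig, simulate_reports

cells = st.integers(min_value=1, max_value=500)


class TestContingencyTable:
    def test_rejects_negative_and_all_zero(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)

    def test_n_is_cell_sum(self):
        assert ContingencyTable(1, 2, 3, 4).N == 10


class TestRorWithCi:
    def test_perfect_balance_is_unity(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(10, 10, 10, 10))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_zero_exposed_cases_point_estimate_zero(self):
        ror, lo, hi = ror_with_ci(ContingencyTable(0, 100, 50, 1000))
        assert ror == 0.0
        assert 0 < lo < hi  # interval from the corrected table stays finite

    def test_derived_example_against_hand_arithmetic(self):
        # ad/(bc) = 20*890/(80*10) = 22.25; CI = exp(ln ROR +- 1.96*s),
        # s = sqrt(1/20 + 1/80 + 1/10 + 1/890).
        ror, lo, hi = ror_with_ci(ContingencyTable(20, 80, 10, 890))
        s = math.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 890)
        assert ror == pytest.approx(22.25, rel=1e-12)
        assert lo == pytest.approx(22.25 * math.exp(-1.96 * s), rel=1e-12)
        assert hi == pytest.approx(22.25 * math.exp(1.96 * s), rel=1e-12)

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_point_estimate_within_ci(self, a, b, c, d):
        ror, lo, hi = ror_with_ci(ContingencyTable(a, b, c, d))
        assert lo < ror < hi

    @given(a=cells, b=cells, c=cells, d=cells)
    def test_transposition_symmetry(self, a, b, c, d):
        ror1, _, _ = ror_with_ci(ContingencyTable(a, b, c, d))
        ror2, _, _ = ror_with_ci(ContingencyTable(a, c, b, d))
        assert ror1 == pytest.approx(ror2, rel=1e-12)

    @given(a=st.integers(1, 100), b=cells, c=cells, d=cells)
    def test_monotone_in_a(self, a, b, c, d):
        ror1, _, _ = ror_with_ci(ContingencyTable(a, b, c, d))
        ror2, _, _ = ror_with_ci(ContingencyTable(a + 1, b, c, d))
        assert ror2 > ror1


class TestIcWithIc025:
    def test_independence_gives_zero(self):
        # a*N = (a+b)(a+c): 10*1100 = 100*110
        ic, ic025 = ic_with_ic025(ContingencyTable(10, 90, 100, 900))
        assert ic == pytest.approx(0.0, abs=1e-12)
        assert ic025 < 0

    def test_derived_example(self):
        ic, _ = ic_with_ic025(ContingencyTable(20, 80, 10, 890))
        assert ic == pytest.approx(math.log2(20 * 1000 / (100 * 30)), rel=1e-12)

    def test_zero_cell_corrected_finite_negative(self):
        ic, ic025 = ic_with_ic025(ContingencyTable(0, 100, 50, 1000))
        assert math.isfinite(ic) and ic < 0
        assert ic025 < ic

    def test_literal_denominator_differs(self):
        t = ContingencyTable(20, 80, 10, 890)
        ic_default, _ = ic_with_ic025(t)
        ic_literal, _ = ic_with_ic025(t, literal_ic=True)
        assert ic_literal == pytest.approx(math.log2(20 * 1000 / (100 * 900)), rel=1e-12)
        assert ic_default != ic_literal

    @given(a=st.integers(1, 100), b=cells, c=cells, d=cells)
    def test_literal_form_monotone_in_a(self, a, b, c, d):
        # The expected-count IC is not monotone in a on tiny tables (a enters
        # N and both margins: (1,1,1,6) -> (2,1,1,6) lowers it); the literal
        # denominator (a+b)(c+d) is strictly monotone, checked here.
        ic1, _ = ic_with_ic025(ContingencyTable(a, b, c, d), literal_ic=True)
        ic2, _ = ic_with_ic025(ContingencyTable(a + 1, b, c, d), literal_ic=True)
        assert ic2 > ic1


class TestFlagSignal:
    @pytest.mark.parametrize(
        "a,ci_low,ic025,expected",
        [
            (2, 5.0, 2.0, False),   # below the report-count floor
            (10, 1.0, 0.5, False),  # CI bound not strictly above 1
            (10, 1.2, 0.0, False),  # IC025 not strictly above 0
            (10, 1.2, 0.3, True),
            (3, 1.01, 0.01, True),  # boundary count is inclusive
        ],
    )
    def test_three_part_rule(self, a, ci_low, ic025, expected):
        assert flag_signal(a, ci_low, ic025) is expected

    @given(
        a=st.integers(3, 50),
        ci_low=st.floats(1.01, 10),
        ic025=st.floats(0.01, 5),
        da=st.integers(0, 10),
        dlo=st.floats(0, 5),
        dic=st.floats(0, 5),
    )
    def test_monotone_in_each_criterion(self, a, ci_low, ic025, da, dlo, dic):
        assert flag_signal(a, ci_low, ic025)
        assert flag_signal(a + da, ci_low + dlo, ic025 + dic)


class TestBuildContingency:
    def test_exhaustive_four_reports(self, make_report):
        rs = ReportSet.from_reports(
            [
                make_report(0, drug_name="sunitinib", reactions=frozenset({"Hypertension"})),
                make_report(1, drug_name="sunitinib", reactions=frozenset({"Nausea"})),
                make_report(2, drug_name="aspirin", reactions=frozenset({"Hypertension"})),
                make_report(3, drug_name="aspirin", reactions=frozenset({"Nausea"})),
            ]
        )
        t = build_contingency(rs, ["sunitinib"], ["Hypertension"])
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_disjoint_pts_empty_target_cells(self, small_reports):
        t = build_contingency(small_reports, ["sunitinib"], ["Never reported"])
        assert t.a == 0 and t.c == 0

    def test_empty_set_rejected(self, small_reports):
        empty = small_reports.with_frame(small_reports.frame.iloc[0:0])
        with pytest.raises(ValueError):
            build_contingency(empty, ["sunitinib"], ["Hypertension"])

    def test_planted_cells_recovered_exactly(self):
        cfg = FaersSimConfig(n_reports=4000, seed=3)
        rs, truth = simulate_reports(cfg)
        rs = filter_malignancy(deduplicate(rs))
        for key, expected in truth["cells"].items():
            target, group = key.split("|")
            drugs = (
                [d for d in cfg.drug_probs if _class_of(d) == target]
                if target in ("VEGFi", "VEGFRi")
                else [target]
            )
            t = build_contingency(rs, drugs, DEFAULT_PT_GROUPS[group])
            assert (t.a, t.b, t.c, t.d) == tuple(expected)


def _class_of(drug):
    from vegfpv.synthetic import _drug_class

    return _drug_class(drug)


class TestSignalTable:
    def test_single_pair_matches_scalar_pipeline(self, small_reports):
        table = signal_table(small_reports, ["sunitinib"], {"ht": ["Hypertension"]})
        assert len(table) == 1
        t = build_contingency(small_reports, ["sunitinib"], ["Hypertension"])
        r = evaluate_pair(t)
        row = table.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (t.a, t.b, t.c, t.d)
        assert row.ror == pytest.approx(r.ror)
        assert row.ic025 == pytest.approx(r.ic025)
        assert bool(row.is_signal) == r.is_signal

    def test_cardinality_and_order(self, small_reports):
        drugs = ["sunitinib", "bevacizumab", "aspirin"]
        groups = {g: ["Hypertension"] for g in ["g1", "g2", "g3", "g4"]}
        table = signal_table(small_reports, drugs, groups)
        assert len(table) == 12
        assert list(table["drug"]) == sorted(table["drug"])

    def test_planted_signals_recovered(self):
        cfg = FaersSimConfig(
            n_reports=10_000,
            seed=9,
            planted_ror={
                ("sunitinib", "hypertension"): 8.0,
                ("bevacizumab", "hypertension"): 1.0,
            },
        )
        rs, _ = simulate_reports(cfg)
        rs = filter_malignancy(deduplicate(rs))
        table = signal_table(
            rs, ["sunitinib", "bevacizumab"], {"hypertension": DEFAULT_PT_GROUPS["hypertension"]}
        ).set_index("drug")
        assert bool(table.loc["sunitinib", "is_signal"])
        assert not bool(table.loc["bevacizumab", "is_signal"])


class TestPerCancerRor:
    def _prepared(self, seed=13, **kw):
        kw.setdefault("n_reports", 8000)
        cfg = FaersSimConfig(seed=seed, **kw)
        rs, truth = simulate_reports(cfg)
        return filter_malignancy(deduplicate(rs)), truth

    def test_min_case_exclusion_strict_boundary(self, make_report):
        # 4 exposed hypertension cases in one cancer, 5 in another.
        reports = []
        i = 0
        for cancer, n_exposed in [("Breast cancer", 4), ("Colorectal cancer", 5)]:
            for _ in range(n_exposed):
                reports.append(make_report(i, drug_name="sunitinib", indication=cancer)); i += 1
            for _ in range(20):
                reports.append(
                    make_report(i, drug_name="aspirin", indication=cancer,
                                reactions=frozenset({"Nausea"}))
                ); i += 1
        rs = ReportSet.from_reports(reports)
        labels = {"breast cancer": "BRCA", "colorectal cancer": "CRC"}
        out = per_cancer_ror(rs, labels, ["sunitinib"], ["Hypertension"], min_cases=5)
        assert list(out["cancer_type"]) == ["CRC"]
        assert out.iloc[0]["a"] == 5

    def test_planted_per_cancer_ror_within_ci(self):
        rs, truth = self._prepared(
            seed=21,
            n_reports=40_000,
            planted_ror={("VEGFRi", "hypertension"): 6.0},
        )
        labels = truth["cancer_label"]
        from vegfpv.synthetic import VEGFRI

        out = per_cancer_ror(
            rs, labels, sorted(VEGFRI), DEFAULT_PT_GROUPS["hypertension"], min_cases=5
        )
        assert len(out) > 10
        covered = ((out["ci_low"] < 6.0) & (6.0 < out["ci_high"])).mean()
        assert covered >= 0.85  # 95% CIs over ~25 strata; a couple may miss
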