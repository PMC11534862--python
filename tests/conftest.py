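import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from datetime import date

from vegfpv.report_store import CaseReport, ReportSet


def _report(i, **kw):
    base = dict(
        report_id=f"R{i:03d}",
        sex="female",
        age=60.0,
        age_unit="years",
        country="US",
        event_date=date(2020, 3, 1),
        therapy_start_date=date(2020, 1, 1),
        drug_name="sunitinib",
        drug_role="primary_suspect",
        indication="Renal cell carcinoma",
        reactions=frozenset({"Hypertension"}),
    )
    base.update(kw)
    return CaseReport(**base)


@pytest.fixture
def make_report():
    return _report


@pytest.fixture
def small_reports():
    """Ten distinct reports spanning both drug classes and a non-target drug."""
    reports = [
        _report(0, drug_name="bevacizumab", indication="Breast cancer"),
        _report(1, drug_name="bevacizumab", reactions=frozenset({"Nausea"})),
        _report(2, drug_name="sunitinib"),
        _report(3, drug_name="sunitinib", reactions=frozenset({"Fatigue", "Nausea"})),
        _report(4, drug_name="sorafenib", indication="Hepatocellular carcinoma"),
        _report(5, drug_name="aspirin", reactions=frozenset({"Hypertension"})),
        _report(6, drug_name="aspirin", reactions=frozenset({"Nausea"})),
        _report(7, drug_name="ranibizumab", indication="Macular degeneration"),
        _report(8, drug_name="lenvatinib", age=45.0),
        _report(9, drug_name="pazopanib", sex="male", event_date=None),
    ]
    return ReportSet.from_reports(reports, provenance="fixture")


@pytest.fixture
def bp_cohort():
    """Deterministic 6-patient cohort covering all three categories."""
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(6)],
            "drug_class": ["VEGFi"] * 3 + ["VEGFRi"] * 3,
            "sbp_pre": [120.0, 128.0, 135.0, 150.0, 118.0, 125.0],
            "dbp_pre": [75.0, 78.0, 80.0, 95.0, 70.0, 82.0],
            "sbp_post": [150.0, 132.0, 141.0, 152.0, 119.0, 131.0],
            "dbp_post": [95.0, 86.0, 88.0, 96.0, 71.0, 84.0],
        }
    )
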