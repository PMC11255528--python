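import datetime

import pytest
from hypothesis import HealthCheck, settings

from ehrdqa import RawValue, RecordPair
from ehrdqa.variables import SPEC_BY_NAME, VARIABLE_NAMES

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# A fully-present, self-consistent record template: both sources equal.
TEMPLATE = {
    "date_of_birth": "1975-06-15",
    "gender": "F",
    "district": "District 1",
    "sector": "Sector 3",
    "facility_name": "Facility HF001",
    "date_last_visit": "2018-10-20",
    "date_first_positive_test": "2009-03-02",
    "date_enrollment": "2009-04-01",
    "date_first_art": "2009-05-01",
    "who_stage": "Stage II",
    "regimen1_start_date": "2009-05-10",
    "regimen1_drugs": "Tenofovir (300) + Lamivudine (300) + Efavirenz (600)",
    "regimen2_start_date": "",
    "regimen2_drugs": "",
    "regimen3_start_date": "",
    "regimen3_drugs": "",
    "pickup1_date": "2018-10-20",
    "pickup1_drugs": "Tenofovir (300) + Lamivudine (300) + Efavirenz (600)",
    "pickup2_date": "2018-09-18",
    "pickup2_drugs": "Tenofovir (300) + Lamivudine (300) + Efavirenz (600)",
    "pickup3_date": "2018-08-21",
    "pickup3_drugs": "Tenofovir (300) + Lamivudine (300) + Efavirenz (600)",
    "vl1_date": "2018-09-01",
    "vl1_value": "20",
    "vl2_date": "2018-03-01",
    "vl2_value": "150",
    "vl3_date": "2017-09-01",
    "vl3_value": "900",
}


def make_record(patient_id="P1", facility_id="HF001", paper=None, ehr=None,
                **kwargs) -> RecordPair:
    """Build a record from the template; ``paper``/``ehr`` dicts
    override individual cells per source."""
    paper = paper or {}
    ehr = ehr or {}
    values = {}
    for name in VARIABLE_NAMES:
        kind = SPEC_BY_NAME[name].kind
        values[name] = (
            RawValue(paper.get(name, TEMPLATE[name]), kind),
            RawValue(ehr.get(name, TEMPLATE[name]), kind),
        )
    return RecordPair(patient_id=patient_id, facility_id=facility_id,
                      values=values, **kwargs)


@pytest.fixture
def record():
    return make_record()


@pytest.fixture
def collection_date():
    return datetime.date(2018, 12, 1)
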