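from datetime import date

import numpy as np
import pandas as pd
import pytest

from dhsi.cohort import EVENT_COLUMNS


def make_event(patient_id, d, event_type, **kw):
    return {
        "patient_id": patient_id,
        "date": d,
        "event_type": event_type,
        "code": kw.get("code", ""),
        "drug_class": kw.get("drug_class", ""),
        "molecule": kw.get("molecule", ""),
        "daily_dose": kw.get("daily_dose", np.nan),
        "coverage_days": kw.get("coverage_days", np.nan),
        "flags": "",
    }


def events_frame(rows):
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


@pytest.fixture
def qualifying_patient_events():
    """One clean patient: incident citalopram monotherapy on 2008-03-01,
    depression diagnosis nine days later, adult, amply registered."""
    rows = [
        make_event("A", date(2007, 1, 1), "birth_year_record", code="1968"),
        make_event("A", date(2007, 1, 1), "gp_visit"),
        make_event("A", date(2008, 3, 1), "gp_visit"),
        make_event("A", date(2008, 3, 1), "ad_prescription", molecule="citalopram",
                   daily_dose=20.0, coverage_days=30),
        make_event("A", date(2008, 3, 10), "gp_visit"),
        make_event("A", date(2008, 3, 10), "depression_diagnosis", code="DEP"),
        make_event("A", date(2010, 1, 1), "gp_visit"),
    ]
    return events_frame(rows)
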