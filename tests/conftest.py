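import warnings

import pandas as pd
import pytest

from pharmvig_tma.icsr import DrugDictionary, EventSet

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def dictionary() -> DrugDictionary:
    return DrugDictionary.bundled()


@pytest.fixture(scope="session")
def tma_events() -> EventSet:
    return EventSet.bundled_tma()


@pytest.fixture()
def raw_reports() -> pd.DataFrame:
    """Three well-formed raw report rows."""
    return pd.DataFrame({
        "report_id": ["r1", "r2", "r3"],
        "gender": ["female", "male", "unknown"],
        "age_years": [44.9, 45.0, None],
        "region": ["Europe", "Americas", "Asia"],
        "event_date": ["2020-02-05", "2021-06-01", "2019-12-31"],
        "suspect_drugs": ["bevacizumab", "sunitinib", "paclitaxel"],
        "concomitant_drugs": ["", "paclitaxel", ""],
        "indication": ["colon cancer", "renal cell carcinoma", "breast cancer"],
        "events": ["thrombotic microangiopathy", "nausea", "rash;fatigue"],
        "outcome": ["nonfatal", "fatal", "unknown"],
        "therapy_start": ["2020-01-01", "2021-05-01", "2019-11-01"],
        "event_onset": ["2020-02-05", "2021-06-01", "2019-12-31"],
    })
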