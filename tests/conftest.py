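import numpy as np
import pandas as pd
import pytest

from vetharm.codesets import load_registry
from vetharm.comorbidity import load_charlson_mapping


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def charlson():
    return load_charlson_mapping()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_tables(rows):
    """Build (patients, encounters, diagnoses) from compact per-patient specs.

    ``rows``: list of dicts with patient_id, birth_date, and encounters as
    a list of (date, [(code, system), ...]) tuples.
    """
    patients, encounters, diagnoses = [], [], []
    eid = 0
    for spec in rows:
        patients.append(
            {
                "patient_id": spec["patient_id"],
                "birth_date": spec.get("birth_date", "1970-06-15"),
                "sex": spec.get("sex", "M"),
                "race": spec.get("race", "White"),
                "ethnicity": spec.get("ethnicity", "NotHispanic"),
                "marital_status": spec.get("marital_status", "Married"),
                "service_connection_pct": spec.get("service_connection_pct", np.nan),
            }
        )
        for date, codes in spec["encounters"]:
            eid += 1
            encounters.append(
                {
                    "encounter_id": eid,
                    "patient_id": spec["patient_id"],
                    "date": date,
                    "setting": "outpatient",
                }
            )
            for code, system in codes:
                diagnoses.append(
                    {"encounter_id": eid, "code": code, "system": system}
                )
    patients = pd.DataFrame(patients)
    patients["birth_date"] = pd.to_datetime(patients["birth_date"])
    encounters = pd.DataFrame(encounters)
    encounters["date"] = pd.to_datetime(encounters["date"])
    return patients, encounters, pd.DataFrame(diagnoses)
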