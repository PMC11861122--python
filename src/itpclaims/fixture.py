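"""A deterministic hand-written ~20-patient claims fixture.

Each patient exercises one branch of the pipeline: episode merging,
pulse/high-dose therapy, pregnancy-month exclusion, withdrawal and
re-administration, add-on vs switch, splenectomy, look-back failures,
prevalent steroid use, and an adverse-outcome case/washout pair.
"""

from __future__ import annotations

import pandas as pd

from itpclaims.io import ClaimsTables

_OBS = ("2014-04", "2022-08")

# patient_id, gender, birth_year, obs_start, obs_end
_PATIENTS = [
    # eligible, two merged CS scripts, withdrawal event at day 60
    ("P01", "male", 1946, *_OBS),
    # eligible, never treated; ITP codes in May and July only
    ("P02", "female", 1950, *_OBS),
    # excluded: ITP code flagged suspected only
    ("P03", "male", 1940, *_OBS),
    # excluded: age 18 at entry
    ("P04", "female", 1998, *_OBS),
    # excluded: first ITP 2 months after enrollment start
    ("P05", "male", 1948, "2016-01", _OBS[1]),
    # excluded: prevalent CS user (PSL 30 days before entry)
    ("P06", "female", 1952, *_OBS),
    # methylprednisolone pulse at entry, then oral PSL
    ("P07", "male", 1944, *_OBS),
    # pregnancy-with-ITP month excluded from person-time
    ("P08", "female", 1989, *_OBS),
    # withdrawal at day 100 (gap 61), CS re-administered later
    ("P09", "male", 1947, *_OBS),
    # CS then EPAG added on, then EPAG alone
    ("P10", "female", 1949, *_OBS),
    # CS and EPAG started within the combo window
    ("P11", "male", 1951, *_OBS),
    # ROMI weekly injections (date-interval merge rule)
    ("P12", "female", 1943, *_OBS),
    # RTX course of 4 weekly infusions
    ("P13", "male", 1945, *_OBS),
    # CS then splenectomy
    ("P14", "female", 1942, *_OBS),
    # high-dose dexamethasone run only
    ("P15", "male", 1953, *_OBS),
    # treated, infection outcome 123 days after entry
    ("P16", "female", 1948, *_OBS),
    # infection code in look-back: washed out of the infection analysis
    ("P17", "male", 1946, *_OBS),
    # eligible untreated with long follow-up (control pool)
    ("P18", "female", 1944, *_OBS),
    # excluded: first ITP 2 months after database start
    ("P19", "male", 1950, *_OBS),
    # eligible untreated male aged 70, inpatient at entry
    ("P20", "male", 1948, *_OBS),
]

# patient_id, date, code, suspected, inpatient
_DIAGNOSES = [
    ("P01", "2016-03-10", "D693", 0, 0),
    ("P01", "2016-04-15", "D693", 0, 0),
    ("P01", "2016-05-15", "D693", 0, 0),
    ("P01", "2016-06-15", "D693", 0, 0),
    ("P01", "2016-07-15", "D693", 0, 0),
    ("P01", "2016-08-15", "D693", 0, 0),
    ("P01", "2016-01-15", "I10", 0, 0),      # hypertension in look-back
    ("P02", "2017-05-02", "D693", 0, 0),
    ("P02", "2017-07-15", "D693", 0, 0),
    ("P03", "2018-03-10", "D693", 1, 0),
    ("P04", "2016-05-01", "D693", 0, 0),
    ("P05", "2016-03-15", "D693", 0, 0),
    ("P06", "2018-04-10", "D693", 0, 0),
    ("P07", "2017-01-10", "D693", 0, 0),
    ("P07", "2017-02-15", "D693", 0, 0),
    ("P07", "2017-03-15", "D693", 0, 0),
    ("P07", "2017-04-15", "D693", 0, 0),
    ("P07", "2017-05-15", "D693", 0, 0),
    ("P07", "2017-06-15", "D693", 0, 0),
    ("P08", "2019-02-05", "D693", 0, 0),
    ("P08", "2019-03-15", "D693", 0, 0),
    ("P08", "2019-04-15", "D693", 0, 0),
    ("P08", "2019-04-10", "O993", 0, 0),     # pregnancy with ITP
    ("P08", "2019-05-15", "D693", 0, 0),
    ("P08", "2019-06-15", "D693", 0, 0),
    ("P09", "2019-03-01", "D693", 0, 0),
    ("P09", "2019-06-15", "D693", 0, 0),
    ("P09", "2019-09-15", "D693", 0, 0),
    ("P09", "2019-12-15", "D693", 0, 0),
    ("P09", "2020-01-15", "D693", 0, 0),
    ("P10", "2018-01-05", "D693", 0, 0),
    ("P10", "2018-02-15", "D693", 0, 0),
    ("P10", "2018-03-15", "D693", 0, 0),
    ("P10", "2018-04-15", "D693", 0, 0),
    ("P11", "2020-02-01", "D693", 0, 0),
    ("P11", "2020-03-15", "D693", 0, 0),
    ("P12", "2019-05-01", "D693", 0, 0),
    ("P12", "2019-06-15", "D693", 0, 0),
    ("P13", "2017-06-01", "D693", 0, 0),
    ("P13", "2017-07-15", "D693", 0, 0),
    ("P14", "2018-02-01", "D693", 0, 0),
    ("P14", "2018-03-15", "D693", 0, 0),
    ("P14", "2018-04-15", "D693", 0, 0),
    ("P14", "2018-05-15", "D693", 0, 0),
    ("P14", "2018-06-15", "D693", 0, 0),
    ("P14", "2018-07-15", "D693", 0, 0),
    ("P15", "2020-03-05", "D693", 0, 0),
    ("P15", "2020-04-15", "D693", 0, 0),
    ("P16", "2019-05-01", "D693", 0, 0),
    ("P16", "2019-06-15", "D693", 0, 0),
    ("P16", "2019-09-15", "D693", 0, 0),
    ("P16", "2019-12-15", "D693", 0, 0),
    ("P16", "2020-04-15", "D693", 0, 0),
    ("P16", "2019-09-01", "A49", 0, 0),      # infection event, day 123
    ("P17", "2019-04-01", "D693", 0, 0),
    ("P17", "2019-05-15", "D693", 0, 0),
    ("P17", "2019-01-15", "A49", 0, 0),      # infection in look-back
    ("P17", "2019-08-01", "A49", 0, 0),
    ("P18", "2016-02-15", "D693", 0, 0),
    ("P18", "2016-06-15", "D693", 0, 0),
    ("P18", "2016-10-15", "D693", 0, 0),
    ("P18", "2017-02-15", "D693", 0, 0),
    ("P19", "2014-06-01", "D693", 0, 0),
    ("P20", "2018-09-10", "D693", 0, 1),
    ("P20", "2018-10-15", "D693", 0, 0),
    ("P20", "2018-05-01", "E11", 0, 0),      # diabetes in look-back
]

# patient_id, date, drug_class, drug_name, route, daily_dose_mg, days
_PRESCRIPTIONS = [
    ("P01", "2016-03-10", "CS", "prednisolone", "oral", 30.0, 30),
    ("P01", "2016-04-09", "CS", "prednisolone", "oral", 30.0, 30),
    ("P06", "2018-03-11", "CS", "prednisolone", "oral", 20.0, 14),
    ("P07", "2017-01-10", "CS", "methylprednisolone", "injection",
     500.0, 3),
    ("P07", "2017-01-13", "CS", "prednisolone", "oral", 40.0, 30),
    ("P08", "2019-02-05", "CS", "prednisolone", "oral", 10.0, 120),
    ("P09", "2019-03-01", "CS", "prednisolone", "oral", 30.0, 50),
    ("P09", "2019-04-20", "CS", "prednisolone", "oral", 30.0, 50),
    ("P09", "2019-08-09", "CS", "prednisolone", "oral", 20.0, 30),
    ("P10", "2018-01-05", "CS", "prednisolone", "oral", 30.0, 30),
    ("P10", "2018-02-04", "CS", "prednisolone", "oral", 20.0, 30),
    ("P10", "2018-02-04", "EPAG", "eltrombopag", "oral", 25.0, 30),
    ("P10", "2018-03-06", "EPAG", "eltrombopag", "oral", 25.0, 30),
    ("P11", "2020-02-01", "CS", "prednisolone", "oral", 30.0, 30),
    ("P11", "2020-02-08", "EPAG", "eltrombopag", "oral", 25.0, 30),
    ("P12", "2019-05-01", "ROMI", "romiplostim", "injection", 0.25, 1),
    ("P12", "2019-05-08", "ROMI", "romiplostim", "injection", 0.25, 1),
    ("P12", "2019-05-15", "ROMI", "romiplostim", "injection", 0.25, 1),
    ("P13", "2017-06-01", "RTX", "rituximab", "injection", 375.0, 1),
    ("P13", "2017-06-08", "RTX", "rituximab", "injection", 375.0, 1),
    ("P13", "2017-06-15", "RTX", "rituximab", "injection", 375.0, 1),
    ("P13", "2017-06-22", "RTX", "rituximab", "injection", 375.0, 1),
    ("P14", "2018-02-01", "CS", "prednisolone", "oral", 30.0, 30),
    ("P15", "2020-03-05", "CS", "dexamethasone", "oral", 30.0, 4),
    ("P16", "2019-05-01", "CS", "prednisolone", "oral", 30.0, 30),
]

# patient_id, date, procedure
_PROCEDURES = [
    ("P14", "2018-06-15", "splenectomy"),
]

#: patients surviving every selection criterion (hand-enumerated)
ELIGIBLE_IDS = ["P01", "P02", "P07", "P08", "P09", "P10", "P11", "P12",
                "P13", "P14", "P15", "P16", "P17", "P18", "P20"]


def fixture_small() -> ClaimsTables:
    """Build the fixture tables (deterministic, in memory)."""
    patients = pd.DataFrame(
        _PATIENTS, columns=["patient_id", "gender", "birth_year",
                            "observation_start", "observation_end"])
    patients["observation_start"] = pd.PeriodIndex(
        patients["observation_start"], freq="M")
    patients["observation_end"] = pd.PeriodIndex(
        patients["observation_end"], freq="M")
    diagnoses = pd.DataFrame(
        _DIAGNOSES, columns=["patient_id", "date", "code", "suspected",
                             "inpatient"])
    diagnoses["date"] = pd.to_datetime(diagnoses["date"])
    diagnoses["suspected"] = diagnoses["suspected"].astype(bool)
    diagnoses["inpatient"] = diagnoses["inpatient"].astype(bool)
    prescriptions = pd.DataFrame(
        _PRESCRIPTIONS, columns=["patient_id", "date", "drug_class",
                                 "drug_name", "route", "daily_dose_mg",
                                 "days_supplied"])
    prescriptions["date"] = pd.to_datetime(prescriptions["date"])
    procedures = pd.DataFrame(
        _PROCEDURES, columns=["patient_id", "date", "procedure"])
    procedures["date"] = pd.to_datetime(procedures["date"])
    return ClaimsTables(patients, diagnoses, prescriptions, procedures)
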