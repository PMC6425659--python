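"""Shared builders for hand-constructed fixtures."""

from __future__ import annotations

import pandas as pd

from carepath import empty_bundle
from carepath.pathways import Contact
from carepath.records_io import LinkedRecordBundle


def ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


def person(pid, dob="1980-06-15", sex="female", resident=True) -> dict:
    return {
        "person_id": pid,
        "date_of_birth": pd.Timestamp(dob),
        "sex": sex,
        "resident_in_scope": resident,
    }


def call(cid, pid, start, end=None, code="25B03", alcohol=False, drug=False,
         lowest=False, transported=False) -> dict:
    return {
        "contact_id": cid,
        "person_id": pid,
        "start_datetime": pd.Timestamp(start),
        "end_datetime": pd.Timestamp(end) if end else pd.NaT,
        "final_ampds_code": code,
        "alcohol_flag": alcohol,
        "drug_flag": drug,
        "lowest_priority_flag": lowest,
        "transported": transported,
    }


def ed_row(cid, pid, start, end=None, disposition="completed", triage=None) -> dict:
    return {
        "contact_id": cid,
        "person_id": pid,
        "start_datetime": pd.Timestamp(start),
        "end_datetime": pd.Timestamp(end) if end else pd.NaT,
        "disposition": disposition,
        "triage_category": triage,
    }


def adm(cid, pid, start, end=None, ward="acute") -> dict:
    return {
        "contact_id": cid,
        "person_id": pid,
        "start_datetime": pd.Timestamp(start),
        "end_datetime": pd.Timestamp(end) if end else pd.NaT,
        "ward_type": ward,
    }


def death(pid, date, cause="other") -> dict:
    return {
        "person_id": pid,
        "date_of_death": pd.Timestamp(date),
        "cause_category": cause,
    }


def make_bundle(persons=(), calls=(), ed=(), admissions=(), deaths=()) -> LinkedRecordBundle:
    empty = empty_bundle()

    def frame(rows, template):
        if not rows:
            return template
        df = pd.DataFrame(list(rows), columns=list(template.columns))
        if "triage_category" in df.columns:
            df["triage_category"] = df["triage_category"].astype("Int64")
        return df

    return LinkedRecordBundle(
        persons=frame(persons, empty.persons),
        calls=frame(calls, empty.calls),
        ed=frame(ed, empty.ed),
        admissions=frame(admissions, empty.admissions),
        deaths=frame(deaths, empty.deaths),
    )


def contact(cid, cls, start, end=None, pid="P1", code=None, **kw) -> Contact:
    if code is None and cls == "S":
        code = "25B03"
    return Contact(
        contact_id=cid,
        person_id=pid,
        service_class=cls,
        start=pd.Timestamp(start),
        end=pd.Timestamp(end) if end else None,
        ampds_code=code,
        **kw,
    )
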