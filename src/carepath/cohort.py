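"""Mental-health call identification and index-cohort selection.

Ambulance calls are triaged with AMPDS (Advanced Medical Priority Dispatch
System) codes; the *final* code is the one confirmed or amended by the
attending clinician. Ten final codes identify psychiatric emergencies and
self-harm; nine are full five-character codes and one ("23", intentional
poisoning) is a chapter-level entry that, under the default prefix matching
mode, matches any code in chapter 23.

The index cohort is one episode per person: the earliest qualifying call in
the index year, restricted to residents aged 16 or more (the age of legal
capacity) at that call. Exclusions are tallied by reason.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import pandas as pd

from .records_io import LinkedRecordBundle

#: Default inclusion list: final AMPDS code -> description.
AMPDS_INCLUSION_CODES: dict[str, str] = {
    "09E03": "Hanging",
    "17D02J": "Falls, long fall (>= 6 ft / 2 m) - Jumper",
    "17D03J": "Falls, unconscious or not alert - Jumper",
    "23": "Intentional poisoning",
    "25A01": "Psychiatric, non-suicidal without 1st party verification (alert & awake)",
    "25B01": "Psychiatric, serious haemorrhage",
    "25B02": "Psychiatric, minor haemorrhage",
    "25B03": "Psychiatric, threatening suicide",
    "25B04": "Psychiatric, jumper (threatening)",
    "25D01": "Psychiatric, not alert",
}

#: Entries shorter than a full code are chapter-level and may prefix-match.
_CHAPTER_LEN = 2


@dataclasses.dataclass(frozen=True)
class AmpdsInclusionList:
    """The set of final AMPDS codes that define a mental-health call.

    ``match_mode`` is "prefix" (chapter-level entries such as "23" match any
    code starting with them) or "exact" (strict membership only).
    """

    codes: tuple[str, ...] = tuple(AMPDS_INCLUSION_CODES)
    descriptions: tuple[str, ...] = tuple(AMPDS_INCLUSION_CODES.values())
    match_mode: str = "prefix"

    def __post_init__(self):
        if self.match_mode not in ("prefix", "exact"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        if len(self.codes) != len(self.descriptions):
            raise ValueError("codes and descriptions must align")

    def description_for(self, code: str) -> str | None:
        """The inclusion-list description a code falls under, or None."""
        for entry, desc in zip(self.codes, self.descriptions):
            if code == entry:
                return desc
            if (
                self.match_mode == "prefix"
                and len(entry) == _CHAPTER_LEN
                and code.startswith(entry)
            ):
                return desc
        return None


DEFAULT_INCLUSION = AmpdsInclusionList()


def is_mh_code(code: str, inclusion: AmpdsInclusionList = DEFAULT_INCLUSION) -> bool:
    """True iff ``code`` identifies a psychiatric-emergency / self-harm call."""
    if not code:
        raise ValueError("empty AMPDS code")
    return inclusion.description_for(code) is not None


def select_mh_calls(
    bundle: LinkedRecordBundle,
    inclusion: AmpdsInclusionList = DEFAULT_INCLUSION,
    year: int = 2011,
) -> pd.DataFrame:
    """All ambulance calls in ``year`` whose final AMPDS code is on the list.

    Year boundaries are inclusive of Jan 1 00:00 through Dec 31 23:59.
    """
    calls = bundle.calls
    if len(calls) == 0:
        return calls.copy()
    in_year = calls["start_datetime"].dt.year == year
    mh = calls["final_ampds_code"].map(lambda c: inclusion.description_for(c) is not None)
    return calls.loc[in_year & mh].copy()


def age_in_completed_years(dob: pd.Timestamp, at: pd.Timestamp) -> int:
    """Attained age: completed years at ``at`` with birthday-inclusive compare."""
    age = at.year - dob.year
    if (at.month, at.day) < (dob.month, dob.day):
        age -= 1
    return age


def select_index_cohort(
    mh_calls: pd.DataFrame,
    persons: pd.DataFrame,
    year: int,
) -> tuple[pd.DataFrame, Counter]:
    """One index episode per eligible person: earliest qualifying call.

    Persons aged under 16 at that call, non-residents, or persons with no
    usable date of birth are excluded; the second return value tallies
    exclusion reasons, so that |cohort| + sum(tally) = distinct callers.
    """
    cols = ["person_id", "contact_id", "index_datetime", "age_at_index", "sex"]
    if len(mh_calls) == 0:
        return pd.DataFrame(columns=cols), Counter()
    firsts = (
        mh_calls.sort_values(["start_datetime", "contact_id"], kind="mergesort")
        .groupby("person_id", as_index=False)
        .first()
    )
    pinfo = persons.set_index("person_id")
    rows = []
    excluded: Counter = Counter()
    for rec in firsts.itertuples(index=False):
        pid = rec.person_id
        if pid not in pinfo.index:
            excluded["unknown_person"] += 1
            continue
        p = pinfo.loc[pid]
        dob = p["date_of_birth"]
        if pd.isna(dob):
            excluded["unknown_age"] += 1
            continue
        if not bool(p["resident_in_scope"]):
            excluded["non_resident"] += 1
            continue
        age = age_in_completed_years(dob, rec.start_datetime)
        if age < 16:
            excluded["under_16"] += 1
            continue
        rows.append((pid, rec.contact_id, rec.start_datetime, age, p["sex"]))
    cohort = pd.DataFrame(rows, columns=cols)
    return cohort, excluded


def tabulate_reasons(
    mh_calls: pd.DataFrame,
    inclusion: AmpdsInclusionList = DEFAULT_INCLUSION,
    transported_only: bool = False,
) -> pd.DataFrame:
    """Frequency of calls per AMPDS inclusion-list description.

    With ``transported_only`` the table covers only calls flagged as direct
    ambulance-to-ED transfers. Percentages are of the respective total.
    Rows are ordered by descending count, then description.
    """
    calls = mh_calls
    if transported_only and len(calls):
        calls = calls.loc[calls["transported"]]
    if len(calls) == 0:
        return pd.DataFrame(columns=["description", "n", "pct"])
    desc = calls["final_ampds_code"].map(inclusion.description_for)
    counts = desc.value_counts()
    total = int(counts.sum())
    out = pd.DataFrame(
        {"description": counts.index, "n": counts.to_numpy()}
    )
    out["pct"] = 100.0 * out["n"] / total
    out = out.sort_values(
        ["n", "description"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
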