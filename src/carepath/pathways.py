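"""Care-pathway construction: 24-hour chaining, letter coding, classification.

A continuous care pathway is a maximal chain of one person's service contacts
in which each contact starts within 24 hours of the end of the previous one
(of its start, when the previous episode has no recorded end). Contacts are
lettered by service class — S ambulance, E emergency department, A acute
admission, M psychiatric admission — and the pathway is encoded as the
concatenated letters, truncated at 11 characters; e.g. an ambulance
attendance, ED visit, and a return ED visit the next morning encode "SEE".

A pathway containing several mental-health ambulance calls is duplicated,
one row per such call (the row's *anchor*), so "SEESE" with two qualifying S
contacts yields two rows. Classification reads the anchored suffix: "S",
"SE", "SEA", "SEM"/"SM" are named classes, anything else is OTHER.
"""

from __future__ import annotations

import dataclasses
import logging

import pandas as pd

from .cohort import AmpdsInclusionList, DEFAULT_INCLUSION
from .records_io import LinkedRecordBundle

logger = logging.getLogger(__name__)

PATHWAY_CLASSES = ("S", "SE", "SEA", "SEM_SM", "OTHER")
_SUFFIX_TO_CLASS = {"S": "S", "SE": "SE", "SEA": "SEA", "SEM": "SEM_SM", "SM": "SEM_SM"}
_CLASS_RANK = {"S": 0, "E": 1, "A": 2, "M": 3}
MAX_CODE_LEN = 11

MINUTE = pd.Timedelta(minutes=1)


@dataclasses.dataclass(frozen=True, slots=True)
class Contact:
    """One timestamped service contact with its class-specific attributes."""

    contact_id: str
    person_id: str
    service_class: str  # S, E, A or M
    start: pd.Timestamp
    end: pd.Timestamp | None
    ampds_code: str | None = None
    alcohol: bool = False
    lowest_priority: bool = False
    transported: bool = False
    disposition: str | None = None

    @property
    def effective_end(self) -> pd.Timestamp:
        return self.start if self.end is None or pd.isna(self.end) else self.end


@dataclasses.dataclass
class CarePathway:
    """An ordered 24-h-linked contact chain with its letter encoding."""

    person_id: str
    contacts: list[Contact]

    @property
    def letters(self) -> str:
        """Full (untruncated) letter sequence."""
        return "".join(c.service_class for c in self.contacts)

    @property
    def code_string(self) -> str:
        return encode_pathway(self)

    @property
    def start(self) -> pd.Timestamp:
        return self.contacts[0].start


@dataclasses.dataclass
class PathwayRow:
    """One analysis row: a pathway keyed to one of its mental-health calls."""

    pathway: CarePathway
    anchor_index: int

    @property
    def anchor(self) -> Contact:
        return self.pathway.contacts[self.anchor_index]


@dataclasses.dataclass
class IntervalMetrics:
    """Times from the anchor call to subsequent pathway stages; fields are
    None when the corresponding contact type does not occur after the anchor."""

    call_to_ed_minutes: float | None = None
    ed_los_minutes: float | None = None
    acute_los_days: float | None = None
    psych_los_days: float | None = None


def _sort_key(c: Contact):
    # Ties on start time break by class order S < E < A < M (an ambulance
    # logically precedes the ED it delivers to), then contact_id.
    return (c.start, _CLASS_RANK[c.service_class], c.contact_id)


def link_contacts(contacts: list[Contact], gap_hours: float = 24.0) -> list[CarePathway]:
    """Partition one person's contacts into maximal 24-h chains.

    A contact joins the current chain iff its start is at most ``gap_hours``
    after the previous contact's end (exactly 24 h counts as linked).
    Overlapping contacts are chained in start order and logged, not rejected.
    """
    if not contacts:
        return []
    gap = pd.Timedelta(hours=gap_hours)
    ordered = sorted(contacts, key=_sort_key)
    pathways: list[CarePathway] = []
    current = [ordered[0]]
    for c in ordered[1:]:
        prev = current[-1]
        if c.start < prev.start or (
            prev.end is not None and not pd.isna(prev.end) and c.start < prev.end
        ):
            logger.debug(
                "overlapping contacts chained: %s then %s", prev.contact_id, c.contact_id
            )
        if c.start - prev.effective_end <= gap:
            current.append(c)
        else:
            pathways.append(CarePathway(c.person_id, current))
            current = [c]
    pathways.append(CarePathway(ordered[0].person_id, current))
    return pathways


def encode_pathway(pathway: CarePathway) -> str:
    """Concatenated class letters in time order, truncated to 11 characters.

    Contacts beyond the 11th stay attached to the pathway (interval metrics
    still see them) but are absent from the code string.
    """
    if not pathway.contacts:
        raise ValueError("cannot encode an empty pathway")
    return pathway.letters[:MAX_CODE_LEN]


def duplicate_per_mh_call(
    pathways: list[CarePathway],
    inclusion: AmpdsInclusionList = DEFAULT_INCLUSION,
) -> list[PathwayRow]:
    """One row per (pathway, mental-health ambulance call) pair.

    Pathways with no inclusion-list S contact yield no rows.
    """
    rows: list[PathwayRow] = []
    for pw in pathways:
        for i, c in enumerate(pw.contacts):
            if (
                c.service_class == "S"
                and c.ampds_code
                and inclusion.description_for(c.ampds_code) is not None
            ):
                rows.append(PathwayRow(pw, i))
    return rows


def classify_pathway(code_string: str, anchor_position: int = 0) -> str:
    """Five-way class of the anchored suffix of a pathway code string.

    The suffix from the anchor (anchor letter included) is matched exactly:
    "S" -> S, "SE" -> SE, "SEA" -> SEA, "SEM" or "SM" -> SEM_SM; anything
    else -> OTHER. The anchor must be an ambulance contact ("S").
    """
    if not code_string:
        raise ValueError("empty code string")
    bad = set(code_string) - set(_CLASS_RANK)
    if bad:
        raise ValueError(f"invalid letters in code string: {sorted(bad)}")
    if anchor_position < 0 or anchor_position >= len(code_string):
        raise ValueError("anchor position outside code string")
    if code_string[anchor_position] != "S":
        raise ValueError("anchor must be an ambulance call (letter 'S')")
    suffix = code_string[anchor_position:]
    return _SUFFIX_TO_CLASS.get(suffix, "OTHER")


def classify_row(row: PathwayRow) -> str:
    """Class of a pathway row, read from the anchored suffix of the full
    letter sequence truncated to 11 letters."""
    letters = row.pathway.letters
    suffix = letters[row.anchor_index : row.anchor_index + MAX_CODE_LEN]
    return _SUFFIX_TO_CLASS.get(suffix, "OTHER")


def interval_metrics(row: PathwayRow) -> IntervalMetrics:
    """Times from the anchor call to the first subsequent E, A and M contacts.

    ED times in minutes; admission lengths of stay in days. Interval metrics
    use all contacts, including any beyond the code-string truncation.
    """
    anchor = row.anchor
    out = IntervalMetrics()
    for c in row.pathway.contacts[row.anchor_index + 1 :]:
        if c.service_class == "E" and out.call_to_ed_minutes is None:
            out.call_to_ed_minutes = (c.start - anchor.start) / MINUTE
            if c.end is not None and not pd.isna(c.end):
                out.ed_los_minutes = (c.end - c.start) / MINUTE
        elif c.service_class == "A" and out.acute_los_days is None:
            if c.end is not None and not pd.isna(c.end):
                out.acute_los_days = (c.end - c.start) / pd.Timedelta(days=1)
        elif c.service_class == "M" and out.psych_los_days is None:
            if c.end is not None and not pd.isna(c.end):
                out.psych_los_days = (c.end - c.start) / pd.Timedelta(days=1)
    return out


def bundle_contacts(bundle: LinkedRecordBundle, person_ids=None) -> dict[str, list[Contact]]:
    """Unify the three contact tables into per-person Contact lists."""
    keep = None if person_ids is None else set(person_ids)
    by_person: dict[str, list[Contact]] = {}

    def add(c: Contact):
        by_person.setdefault(c.person_id, []).append(c)

    for rec in bundle.calls.itertuples(index=False):
        if keep is not None and rec.person_id not in keep:
            continue
        add(
            Contact(
                rec.contact_id,
                rec.person_id,
                "S",
                rec.start_datetime,
                rec.end_datetime,
                ampds_code=rec.final_ampds_code,
                alcohol=bool(rec.alcohol_flag),
                lowest_priority=bool(rec.lowest_priority_flag),
                transported=bool(rec.transported),
            )
        )
    for rec in bundle.ed.itertuples(index=False):
        if keep is not None and rec.person_id not in keep:
            continue
        add(
            Contact(
                rec.contact_id,
                rec.person_id,
                "E",
                rec.start_datetime,
                rec.end_datetime,
                disposition=rec.disposition,
            )
        )
    for rec in bundle.admissions.itertuples(index=False):
        if keep is not None and rec.person_id not in keep:
            continue
        cls = "A" if rec.ward_type == "acute" else "M"
        add(
            Contact(
                rec.contact_id,
                rec.person_id,
                cls,
                rec.start_datetime,
                rec.end_datetime,
            )
        )
    return by_person


def _terminal_ed(row: PathwayRow) -> Contact | None:
    """The last post-anchor contact if it is an ED attendance, else None."""
    post = row.pathway.contacts[row.anchor_index :]
    last = post[-1]
    return last if last.service_class == "E" else None


def derive_pathway_rows(
    bundle: LinkedRecordBundle,
    person_ids=None,
    inclusion: AmpdsInclusionList = DEFAULT_INCLUSION,
    gap_hours: float = 24.0,
) -> pd.DataFrame:
    """Full pathway-row derivation for a bundle: link, encode, duplicate,
    classify and measure. Returns one row per mental-health call.

    Columns: person_id, anchor_contact_id, anchor_datetime, code_string,
    pathway_class, alcohol_at_anchor, lowest_priority_at_anchor, ed_ending,
    selfdischarge, plus the four interval metrics.
    ``ed_ending`` marks rows whose pathway ends (post anchor) at an ED
    attendance — the denominator for self-discharge analyses; for those rows
    ``selfdischarge`` and ``terminal_ed_los_min`` read that final attendance.
    """
    by_person = bundle_contacts(bundle, person_ids)
    records = []
    for pid in sorted(by_person):
        pathways = link_contacts(by_person[pid], gap_hours=gap_hours)
        for row in duplicate_per_mh_call(pathways, inclusion):
            metrics = interval_metrics(row)
            term = _terminal_ed(row)
            ed_ending = term is not None and term.disposition in (
                "completed",
                "self_discharge",
            )
            sd = bool(ed_ending and term.disposition == "self_discharge")
            term_los = None
            if ed_ending and term.end is not None and not pd.isna(term.end):
                term_los = (term.end - term.start) / MINUTE
            records.append(
                {
                    "person_id": pid,
                    "anchor_contact_id": row.anchor.contact_id,
                    "anchor_datetime": row.anchor.start,
                    "code_string": row.pathway.code_string,
                    "pathway_class": classify_row(row),
                    "alcohol_at_anchor": row.anchor.alcohol,
                    "lowest_priority_at_anchor": row.anchor.lowest_priority,
                    "ed_ending": ed_ending,
                    "selfdischarge": sd,
                    "terminal_ed_los_min": term_los,
                    "call_to_ed_minutes": metrics.call_to_ed_minutes,
                    "ed_los_minutes": metrics.ed_los_minutes,
                    "acute_los_days": metrics.acute_los_days,
                    "psych_los_days": metrics.psych_los_days,
                }
            )
    cols = [
        "person_id",
        "anchor_contact_id",
        "anchor_datetime",
        "code_string",
        "pathway_class",
        "alcohol_at_anchor",
        "lowest_priority_at_anchor",
        "ed_ending",
        "selfdischarge",
        "terminal_ed_los_min",
        "call_to_ed_minutes",
        "ed_los_minutes",
        "acute_los_days",
        "psych_los_days",
    ]
    return pd.DataFrame(records, columns=cols)
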