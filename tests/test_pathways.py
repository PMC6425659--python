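"""Chaining, encoding, duplication, classification and interval metrics."""

import itertools

import pandas as pd
import pytest

import carepath as cp
from carepath.pathways import (
    MAX_CODE_LEN,
    PATHWAY_CLASSES,
    PathwayRow,
    classify_row,
)

from util import contact


HOUR = pd.Timedelta(hours=1)


def _chain_ok(prev, nxt, gap_hours=24.0):
    return nxt.start - prev.effective_end <= pd.Timedelta(hours=gap_hours)


def brute_force_partitions(contacts, gap_hours=24.0):
    """All valid maximal-chain partitions of a sorted contact sequence,
    by exhaustive enumeration of break positions."""
    n = len(contacts)
    valid = []
    for breaks in itertools.product([False, True], repeat=n - 1):
        blocks, cur = [], [contacts[0]]
        ok = True
        for i, brk in enumerate(breaks):
            if brk:
                blocks.append(cur)
                cur = [contacts[i + 1]]
            else:
                cur.append(contacts[i + 1])
        blocks.append(cur)
        for block in blocks:
            for a, b in zip(block, block[1:]):
                if not _chain_ok(a, b, gap_hours):
                    ok = False
        for b1, b2 in zip(blocks, blocks[1:]):  # maximality at boundaries
            if _chain_ok(b1[-1], b2[0], gap_hours):
                ok = False
        if ok:
            valid.append([[c.contact_id for c in b] for b in blocks])
    return valid


def _contacts_from_gaps(gaps, classes=None, with_ends=True):
    classes = classes or ["S"] * (len(gaps) + 1)
    t = pd.Timestamp("2011-03-01T08:00")
    out = []
    for i, cls in enumerate(classes):
        end = t + pd.Timedelta(minutes=30) if with_ends else None
        out.append(
            contact(f"C{i}", cls, t, end, code="25B03" if cls == "S" else None)
        )
        if i < len(gaps):
            t = (end if with_ends else t) + gaps[i]
    return out


def test_single_contact_single_pathway():
    pws = cp.link_contacts([contact("C1", "S", "2011-03-01T08:00", "2011-03-01T08:30")])
    assert len(pws) == 1 and pws[0].code_string == "S"


def test_worked_example_see_chain():
    # S, then E 20 h after S ends, then a second E 3 h after the first ends
    contacts = _contacts_from_gaps([20 * HOUR, 3 * HOUR], ["S", "E", "E"])
    pws = cp.link_contacts(contacts)
    assert len(pws) == 1
    assert pws[0].code_string == "SEE"


def test_gap_over_24h_splits():
    contacts = _contacts_from_gaps([25 * HOUR], ["S", "E"])
    pws = cp.link_contacts(contacts)
    assert [p.code_string for p in pws] == ["S", "E"]


def test_exactly_24h_counts_as_linked():
    contacts = _contacts_from_gaps([24 * HOUR], ["S", "E"])
    assert [p.code_string for p in cp.link_contacts(contacts)] == ["SE"]


@pytest.mark.parametrize("n_contacts", [2, 3, 4, 5])
@pytest.mark.parametrize("with_ends", [True, False])
def test_chaining_matches_brute_force_oracle(n_contacts, with_ends):
    """link_contacts agrees with exhaustive partition enumeration over a
    grid of boundary-straddling gaps for all sequences up to 5 contacts."""
    gap_grid = [HOUR, 23 * HOUR, 24 * HOUR, 25 * HOUR, 60 * HOUR]
    for gaps in itertools.product(gap_grid, repeat=n_contacts - 1):
        contacts = _contacts_from_gaps(list(gaps), with_ends=with_ends)
        got = [
            [c.contact_id for c in p.contacts]
            for p in cp.link_contacts(contacts)
        ]
        expected = brute_force_partitions(contacts)
        assert len(expected) == 1, "oracle must be unique"
        assert got == expected[0]


def test_link_contacts_is_a_partition(small_bundle):
    from carepath.pathways import bundle_contacts

    by_person = bundle_contacts(small_bundle)
    for pid, contacts in list(by_person.items())[:200]:
        pws = cp.link_contacts(contacts)
        flattened = [c.contact_id for p in pws for c in p.contacts]
        assert sorted(flattened) == sorted(c.contact_id for c in contacts)
        # chronological: each pathway starts after the previous one
        starts = [p.start for p in pws]
        assert starts == sorted(starts)


def test_overlapping_contacts_are_chained_not_rejected():
    contacts = [
        contact("C1", "S", "2011-03-01T08:00", "2011-03-01T09:00"),
        contact("C2", "E", "2011-03-01T08:30", "2011-03-01T12:00"),
    ]
    assert [p.code_string for p in cp.link_contacts(contacts)] == ["SE"]


def test_encode_truncates_at_eleven():
    classes = ["S", "E"] * 6 + ["S"]  # 13 contacts alternating
    contacts = _contacts_from_gaps([HOUR] * 12, classes)
    pws = cp.link_contacts(contacts)
    assert len(pws) == 1
    assert pws[0].code_string == "SESESESESES"
    assert len(pws[0].code_string) == MAX_CODE_LEN
    assert len(pws[0].contacts) == 13  # contacts stay attached


def test_duplicate_per_mh_call():
    classes = ["S", "E", "E", "S", "E"]
    contacts = _contacts_from_gaps([HOUR] * 4, classes)
    pws = cp.link_contacts(contacts)
    assert pws[0].code_string == "SEESE"
    rows = cp.duplicate_per_mh_call(pws)
    assert len(rows) == 2
    assert [r.anchor_index for r in rows] == [0, 3]


def test_duplicate_skips_non_inclusion_codes():
    contacts = _contacts_from_gaps([HOUR, HOUR], ["S", "E", "A"])
    contacts[0] = contact("C0", "S", contacts[0].start, contacts[0].end, code="12D01")
    pws = cp.link_contacts(contacts)
    assert cp.duplicate_per_mh_call(pws) == []


def test_classification_named_classes():
    assert cp.classify_pathway("S") == "S"
    assert cp.classify_pathway("SE") == "SE"
    assert cp.classify_pathway("SEA") == "SEA"
    assert cp.classify_pathway("SEM") == "SEM_SM"
    assert cp.classify_pathway("SM") == "SEM_SM"
    assert cp.classify_pathway("SEE") == "OTHER"


def test_classification_matches_enumeration_and_is_total():
    """Exhaustive check of the five-way rule over every suffix up to
    length 3; classes are mutually exclusive and exhaustive."""
    named = {"S": "S", "SE": "SE", "SEA": "SEA", "SEM": "SEM_SM", "SM": "SEM_SM"}
    for length in (1, 2, 3):
        for letters in itertools.product("SEAM", repeat=length):
            suffix = "".join(letters)
            if suffix[0] != "S":
                with pytest.raises(ValueError):
                    cp.classify_pathway(suffix)
                continue
            got = cp.classify_pathway(suffix)
            assert got == named.get(suffix, "OTHER")
            assert got in PATHWAY_CLASSES


def test_classification_anchor_position():
    # anchored suffix of "SEESE" at the second S is "SE"
    assert cp.classify_pathway("SEESE", 3) == "SE"
    assert cp.classify_pathway("SEESE", 0) == "OTHER"
    with pytest.raises(ValueError):
        cp.classify_pathway("SEESE", 1)  # anchor must be an S


def test_interval_metrics_arithmetic():
    contacts = [
        contact("C1", "S", "2011-03-01T10:00", "2011-03-01T10:20"),
        contact("C2", "E", "2011-03-01T10:40", "2011-03-01T13:00"),
    ]
    row = PathwayRow(cp.link_contacts(contacts)[0], 0)
    m = cp.interval_metrics(row)
    assert m.call_to_ed_minutes == 40
    assert m.ed_los_minutes == 140
    assert m.acute_los_days is None and m.psych_los_days is None


def test_interval_metrics_admission_days():
    contacts = [
        contact("C1", "S", "2011-03-01T10:00", "2011-03-01T10:20"),
        contact("C2", "E", "2011-03-01T11:00", "2011-03-01T13:00"),
        contact("C3", "A", "2011-03-01T14:00", "2011-03-03T14:00"),
    ]
    row = PathwayRow(cp.link_contacts(contacts)[0], 0)
    m = cp.interval_metrics(row)
    assert m.acute_los_days == 2.0


def test_interval_metrics_s_only_all_absent():
    row = PathwayRow(
        cp.link_contacts([contact("C1", "S", "2011-03-01T10:00")])[0], 0
    )
    m = cp.interval_metrics(row)
    assert all(
        v is None
        for v in (m.call_to_ed_minutes, m.ed_los_minutes, m.acute_los_days, m.psych_los_days)
    )


def test_generated_index_rows_reproduce_intended_classes(small_bundle, small_config):
    """Re-deriving pathways from a generated bundle yields class labels whose
    mixture matches the generator's configured mixture (structural validity)."""
    res = cp.analyze_bundle(small_bundle, small_config.index_year)
    mix = res.index_rows["pathway_class"].value_counts(normalize=True)
    for cls, target in small_config.pathway_mixture.items():
        se = (target * (1 - target) / len(res.index_rows)) ** 0.5
        assert abs(mix.get(cls, 0.0) - target) < 4 * se + 0.01
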