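"""Person-period conversion, repeat counting, mortality windows and the
self-discharge tables."""

import pandas as pd
import pytest

import carepath as cp
from carepath.followup import REPEAT_BIN_LABELS, repeat_bin

from util import call, death, make_bundle, person


def _index_rows(entries):
    """entries: list of dicts with at least person_id + anchor_datetime."""
    rows = []
    for e in entries:
        rows.append(
            {
                "person_id": e["person_id"],
                "anchor_datetime": pd.Timestamp(e["anchor_datetime"]),
                "pathway_class": e.get("pathway_class", "SE"),
                "ed_ending": e.get("ed_ending", True),
                "selfdischarge": e.get("selfdischarge", False),
                "alcohol_at_anchor": e.get("alcohol", False),
            }
        )
    return pd.DataFrame(rows)


def _calls(entries):
    return make_bundle(
        persons=[person(pid) for pid in {e[1] for e in entries}],
        calls=[call(f"C{i}", pid, t) for i, (t, pid) in enumerate(entries)],
    ).calls


def test_repeat_binning_rule():
    assert repeat_bin(0) == "0"
    assert repeat_bin(4) == "4"
    assert repeat_bin(5) == "5-9"
    assert repeat_bin(9) == "5-9"
    assert repeat_bin(14) == "10-14"
    assert repeat_bin(17) == ">=15"
    assert repeat_bin(101) == ">=15"


def test_person_period_counts_window():
    idx = _index_rows([{"person_id": "P1", "anchor_datetime": "2011-01-05T10:00"}])
    calls = _calls(
        [
            ("2011-01-05T10:00", "P1"),  # the index call itself: not a repeat
            ("2011-04-15T10:00", "P1"),  # day 100
            ("2012-02-09T10:00", "P1"),  # day 400: outside window
        ]
    )
    pp = cp.to_person_period(idx, calls)
    assert pp.loc[0, "n_repeats_1yr"] == 1
    assert pp.loc[0, "repeat_bin"] == "1"
    assert len(pp.loc[0, "call_datetimes"]) == 2  # all-time list keeps day 400


def test_person_period_window_boundary_inclusive_365():
    idx = _index_rows([{"person_id": "P1", "anchor_datetime": "2011-01-01T10:00"}])
    calls = _calls(
        [("2012-01-01T10:00", "P1"), ("2012-01-01T10:01", "P1")]  # day 365, 365+1min
    )
    pp = cp.to_person_period(idx, calls)
    assert pp.loc[0, "n_repeats_1yr"] == 1


def test_person_period_index_only():
    idx = _index_rows([{"person_id": "P1", "anchor_datetime": "2011-01-05T10:00"}])
    pp = cp.to_person_period(idx, _calls([("2011-01-05T10:00", "P1")]))
    assert pp.loc[0, "n_repeats_1yr"] == 0
    assert pp.loc[0, "repeat_bin"] == "0"


def test_person_period_17_repeats_top_bin():
    times = [(f"2011-{m:02d}-{d:02d}T10:00", "P1") for m in range(2, 8) for d in (3, 12, 21)][:17]
    idx = _index_rows([{"person_id": "P1", "anchor_datetime": "2011-01-05T10:00"}])
    pp = cp.to_person_period(idx, _calls(times))
    assert pp.loc[0, "n_repeats_1yr"] == 17
    assert pp.loc[0, "repeat_bin"] == ">=15"


def test_person_period_rejects_duplicate_index_rows():
    idx = _index_rows(
        [
            {"person_id": "P1", "anchor_datetime": "2011-01-05T10:00"},
            {"person_id": "P1", "anchor_datetime": "2011-02-05T10:00"},
        ]
    )
    with pytest.raises(ValueError, match="multiple index rows"):
        cp.to_person_period(idx, _calls([]))


def test_repeat_distribution_counts_and_percentages():
    idx = _index_rows(
        [{"person_id": f"P{i}", "anchor_datetime": "2011-01-05T10:00"} for i in range(4)]
    )
    calls = _calls([("2011-03-01T10:00", "P0"), ("2011-03-02T10:00", "P0"),
                    ("2011-03-01T10:00", "P1")])
    dist = cp.repeat_distribution(cp.to_person_period(idx, calls))
    assert list(dist["repeat_bin"]) == list(REPEAT_BIN_LABELS)
    assert dist["n"].sum() == 4
    assert dist.loc[dist["repeat_bin"] == "0", "n"].item() == 2
    assert dist["pct"].sum() == pytest.approx(100)


def test_repeat_distribution_empty():
    idx = _index_rows([])
    assert len(cp.repeat_distribution(cp.to_person_period(idx, _calls([])))) == 0


def test_mortality_window_boundaries():
    idx = _index_rows(
        [
            {"person_id": "P1", "anchor_datetime": "2011-01-10T15:00"},
            {"person_id": "P2", "anchor_datetime": "2011-01-10T15:00"},
            {"person_id": "P3", "anchor_datetime": "2011-01-10T15:00"},
            {"person_id": "P4", "anchor_datetime": "2011-01-10T15:00"},
        ]
    )
    deaths = make_bundle(
        persons=[person(p) for p in ("P1", "P2", "P3", "P4")],
        deaths=[
            death("P1", "2011-01-11", cause="suicide"),   # next day: within 1 day
            death("P2", "2011-01-12"),                     # day 2: late
            death("P3", "2012-01-10"),                     # day 365: late
            death("P4", "2012-01-11"),                     # day 366: outside
        ],
    ).deaths
    out, summary = cp.mortality_outcomes(idx, deaths)
    by = out.set_index("person_id")
    assert by.loc["P1", "died_within_1day"] and not by.loc["P1", "died_1day_to_1yr"]
    assert by.loc["P2", "died_1day_to_1yr"]
    assert by.loc["P3", "died_1day_to_1yr"]
    assert not by.loc["P4", "died_within_1day"] and not by.loc["P4", "died_1day_to_1yr"]
    assert summary.deaths_1yr == 3 == summary.deaths_1d + summary.deaths_late
    assert summary.suicides_1yr == 1
    assert by.loc["P4", "cause_category"] is None  # cause present iff died in window


def test_mortality_death_before_index_flagged():
    idx = _index_rows([{"person_id": "P1", "anchor_datetime": "2011-06-10T15:00"}])
    deaths = make_bundle(
        persons=[person("P1")], deaths=[death("P1", "2011-01-01")]
    ).deaths
    out, summary = cp.mortality_outcomes(idx, deaths)
    assert summary.flagged_persons == ["P1"]
    assert not out.loc[0, "died_within_1day"] and not out.loc[0, "died_1day_to_1yr"]


def test_mortality_no_deaths():
    idx = _index_rows([{"person_id": "P1", "anchor_datetime": "2011-06-10T15:00"}])
    out, summary = cp.mortality_outcomes(idx, cp.empty_bundle().deaths)
    assert not out[["died_within_1day", "died_1day_to_1yr"]].any().any()
    assert summary.deaths_1yr == 0


def test_mortality_class_marginals_reconcile(small_bundle, small_config):
    res = cp.analyze_bundle(small_bundle, small_config.index_year)
    ms = res.mortality_summary
    assert ms.by_class["deaths_1d"].sum() == ms.deaths_1d
    assert ms.by_class["deaths_late"].sum() == ms.deaths_late
    assert ms.by_class["n"].sum() == ms.n_persons == res.n_cohort
    # categories mutually exclusive
    both = res.mortality["died_within_1day"] & res.mortality["died_1day_to_1yr"]
    assert not both.any()


def test_translation_invariance(small_config):
    """Shifting every timestamp in a bundle by a constant leaves all
    follow-up counts unchanged."""
    bundle = cp.generate_bundle(
        cp.default_config(n_persons=150, seed=9, index_year=2011)
    )
    # 2011->2019 and 2012->2020 have matching leap structure, so an 8-year
    # shift translates every interval exactly while keeping the index window
    # inside a single calendar year.
    shift = pd.DateOffset(years=8)
    shifted = cp.LinkedRecordBundle(
        persons=bundle.persons.assign(
            date_of_birth=bundle.persons["date_of_birth"] + shift
        ),
        calls=bundle.calls.assign(
            start_datetime=bundle.calls["start_datetime"] + shift,
            end_datetime=bundle.calls["end_datetime"] + shift,
        ),
        ed=bundle.ed.assign(
            start_datetime=bundle.ed["start_datetime"] + shift,
            end_datetime=bundle.ed["end_datetime"] + shift,
        ),
        admissions=bundle.admissions.assign(
            start_datetime=bundle.admissions["start_datetime"] + shift,
            end_datetime=bundle.admissions["end_datetime"] + shift,
        ),
        deaths=bundle.deaths.assign(
            date_of_death=bundle.deaths["date_of_death"] + shift
        ),
    )
    res = cp.analyze_bundle(bundle, 2011)
    res_shifted = cp.analyze_bundle(shifted, 2019)
    pd.testing.assert_frame_equal(
        res.repeat_dist, res_shifted.repeat_dist, check_dtype=False
    )
    assert res.mortality_summary.deaths_1d == res_shifted.mortality_summary.deaths_1d
    assert res.mortality_summary.deaths_late == res_shifted.mortality_summary.deaths_late


def test_selfdischarge_tables_structure():
    idx = _index_rows(
        [
            {"person_id": "P1", "anchor_datetime": "2011-01-05T10:00", "selfdischarge": True},
            {"person_id": "P2", "anchor_datetime": "2011-01-05T10:00"},
            {"person_id": "P3", "anchor_datetime": "2011-01-05T10:00", "alcohol": True,
             "selfdischarge": True},
            {"person_id": "P4", "anchor_datetime": "2011-01-05T10:00", "ed_ending": False,
             "pathway_class": "S"},
        ]
    )
    calls = _calls([("2011-03-01T10:00", "P1")])
    pp = cp.to_person_period(idx, calls)
    tables = cp.selfdischarge_analysis(pp, idx)
    t = tables.repeat_table
    assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 1)  # P4 (non-ED-ending) excluded
    t2 = tables.alcohol_table
    assert (t2.a, t2.b, t2.c, t2.d) == (1, 0, 1, 1)


def test_selfdischarge_degenerate_flagged():
    idx = _index_rows(
        [{"person_id": "P1", "anchor_datetime": "2011-01-05T10:00", "selfdischarge": True}]
    )
    pp = cp.to_person_period(idx, _calls([]))
    tables = cp.selfdischarge_analysis(pp, idx)
    assert tables.repeat_degenerate and tables.repeat_table is None
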