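"""Follow-up analyses: person-period conversion, repeat-attendance counting,
one-year mortality, and the self-discharge contingency tables.

Repeat attendances are, by default, *all-cause* ambulance calls made after
the index call — repeat calls need not themselves carry a mental-health
code (an MH-only mode is available). "Within 1 year" means at most 365 days
after the index timestamp; "within 1 day" of death means on the index
calendar date or the next one.
"""

from __future__ import annotations

import dataclasses
import logging

import pandas as pd

from .cohort import AmpdsInclusionList, DEFAULT_INCLUSION
from .stats import TwoByTwoTable

logger = logging.getLogger(__name__)

#: Repeat-count bins in reporting order: (label, low, high); high None = open.
REPEAT_BINS: tuple[tuple[str, int, int | None], ...] = (
    ("0", 0, 0),
    ("1", 1, 1),
    ("2", 2, 2),
    ("3", 3, 3),
    ("4", 4, 4),
    ("5-9", 5, 9),
    ("10-14", 10, 14),
    (">=15", 15, None),
)
REPEAT_BIN_LABELS = tuple(label for label, _, _ in REPEAT_BINS)


def repeat_bin(n: int) -> str:
    """Bin label for a repeat count."""
    if n < 0:
        raise ValueError("repeat count must be nonnegative")
    for label, lo, hi in REPEAT_BINS:
        if n >= lo and (hi is None or n <= hi):
            return label
    raise AssertionError("bins are exhaustive")


def to_person_period(
    index_rows: pd.DataFrame,
    calls: pd.DataFrame,
    window_days: int = 365,
    mh_only: bool = False,
    inclusion: AmpdsInclusionList = DEFAULT_INCLUSION,
) -> pd.DataFrame:
    """One row per cohort person with their post-index call history.

    ``index_rows`` holds one pathway row per person (the row anchored at the
    index call) with columns person_id, anchor_datetime, pathway_class,
    ed_ending, selfdischarge, alcohol_at_anchor. All of that person's
    subsequent ambulance calls (any cause unless ``mh_only``) are collected;
    ``n_repeats_1yr`` counts those within ``window_days`` of the index call.
    """
    cols = [
        "person_id",
        "index_datetime",
        "call_datetimes",
        "n_repeats_1yr",
        "repeat_bin",
        "pathway_class",
        "ed_ending_at_index",
        "had_selfdischarge_at_index",
        "alcohol_at_index",
    ]
    if len(index_rows) == 0:
        return pd.DataFrame(columns=cols)
    dup = index_rows["person_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"multiple index rows for person(s) {sorted(index_rows.loc[dup, 'person_id'])[:5]}"
        )
    pool = calls
    if mh_only and len(pool):
        pool = pool.loc[
            pool["final_ampds_code"].map(
                lambda c: inclusion.description_for(c) is not None
            )
        ]
    idx = index_rows.set_index("person_id")
    window = pd.Timedelta(days=window_days)
    later: dict[str, list[pd.Timestamp]] = {pid: [] for pid in idx.index}
    if len(pool):
        sub = pool.loc[pool["person_id"].isin(idx.index), ["person_id", "start_datetime"]]
        for pid, t in sub.itertuples(index=False):
            if t > idx.at[pid, "anchor_datetime"]:
                later[pid].append(t)
    rows = []
    for pid, rec in idx.iterrows():
        times = sorted(later[pid])
        t0 = rec["anchor_datetime"]
        n_rep = sum(1 for t in times if t - t0 <= window)
        rows.append(
            {
                "person_id": pid,
                "index_datetime": t0,
                "call_datetimes": times,
                "n_repeats_1yr": n_rep,
                "repeat_bin": repeat_bin(n_rep),
                "pathway_class": rec.get("pathway_class"),
                "ed_ending_at_index": bool(rec.get("ed_ending", False)),
                "had_selfdischarge_at_index": bool(rec.get("selfdischarge", False)),
                "alcohol_at_index": bool(rec.get("alcohol_at_anchor", False)),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def repeat_distribution(person_period: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per repeat bin, in reporting order."""
    if len(person_period) == 0:
        return pd.DataFrame(columns=["repeat_bin", "n", "pct"])
    counts = person_period["repeat_bin"].value_counts()
    total = len(person_period)
    out = pd.DataFrame(
        {
            "repeat_bin": REPEAT_BIN_LABELS,
            "n": [int(counts.get(label, 0)) for label in REPEAT_BIN_LABELS],
        }
    )
    out["pct"] = 100.0 * out["n"] / total
    return out


@dataclasses.dataclass
class MortalitySummary:
    """Cross-tabulated one-year mortality by pathway class plus the derived
    headline quantities."""

    by_class: pd.DataFrame  # rows per class: n, deaths_1d, deaths_late
    n_persons: int
    deaths_1d: int
    deaths_late: int
    deaths_1yr: int
    suicides_1yr: int
    suicides_late: int
    late_deaths_s_se: int
    late_suicides_s_se: int
    flagged_persons: list[str]


def mortality_outcomes(
    index_rows: pd.DataFrame,
    deaths: pd.DataFrame,
    window_days: int = 365,
) -> tuple[pd.DataFrame, MortalitySummary]:
    """Per-person one-year mortality outcomes and the class-level summary.

    A death on the index calendar date or the following day counts as
    "within 1 day"; a later death within ``window_days`` of the index date
    counts as "> 1 day and < 1 year". The two are mutually exclusive. A death
    dated before the index date is flagged and not categorized.
    """
    dmap = deaths.set_index("person_id")
    if dmap.index.duplicated().any():
        raise ValueError("multiple death records per person; validate the bundle")
    one_day = pd.Timedelta(days=1)
    window = pd.Timedelta(days=window_days)
    rows = []
    flagged = []
    for rec in index_rows.itertuples(index=False):
        pid = rec.person_id
        died_1d = died_late = False
        cause = None
        if pid in dmap.index:
            ddate = dmap.at[pid, "date_of_death"]
            index_date = rec.anchor_datetime.normalize()
            if ddate < index_date:
                flagged.append(pid)
                logger.warning("death before index date for %s", pid)
            elif ddate <= index_date + one_day:
                died_1d = True
                cause = dmap.at[pid, "cause_category"]
            elif ddate <= index_date + window:
                died_late = True
                cause = dmap.at[pid, "cause_category"]
        rows.append(
            {
                "person_id": pid,
                "pathway_class": rec.pathway_class,
                "died_within_1day": died_1d,
                "died_1day_to_1yr": died_late,
                "cause_category": cause,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "pathway_class",
            "died_within_1day",
            "died_1day_to_1yr",
            "cause_category",
        ],
    )
    if len(out):
        by_class = (
            out.groupby("pathway_class")
            .agg(
                n=("person_id", "size"),
                deaths_1d=("died_within_1day", "sum"),
                deaths_late=("died_1day_to_1yr", "sum"),
            )
            .astype(int)
        )
    else:
        by_class = pd.DataFrame(columns=["n", "deaths_1d", "deaths_late"])
    died_any = out["died_within_1day"] | out["died_1day_to_1yr"]
    suicide = out["cause_category"].eq("suicide")
    s_se = out["pathway_class"].isin(["S", "SE"])
    summary = MortalitySummary(
        by_class=by_class,
        n_persons=len(out),
        deaths_1d=int(out["died_within_1day"].sum()),
        deaths_late=int(out["died_1day_to_1yr"].sum()),
        deaths_1yr=int(died_any.sum()),
        suicides_1yr=int((died_any & suicide).sum()),
        suicides_late=int((out["died_1day_to_1yr"] & suicide).sum()),
        late_deaths_s_se=int((out["died_1day_to_1yr"] & s_se).sum()),
        late_suicides_s_se=int((out["died_1day_to_1yr"] & suicide & s_se).sum()),
        flagged_persons=flagged,
    )
    return out, summary


@dataclasses.dataclass
class SelfDischargeTables:
    """The two exposure/outcome tables behind the self-discharge findings.

    ``repeat_table``: self-discharge at index (exposure) x >=1 repeat call
    (outcome), over persons whose index pathway ended at an ED attendance.
    ``alcohol_table``: alcohol flag on the anchor call (exposure) x
    self-discharge (outcome), over all ED-ending pathway rows.
    A table is None, with its flag set, when an exposure or outcome margin
    is empty (RR undefined).
    """

    repeat_table: TwoByTwoTable | None
    alcohol_table: TwoByTwoTable | None
    repeat_degenerate: bool
    alcohol_degenerate: bool


def _build_2x2(exposed: pd.Series, outcome: pd.Series) -> tuple[TwoByTwoTable | None, bool]:
    a = int((exposed & outcome).sum())
    b = int((exposed & ~outcome).sum())
    c = int((~exposed & outcome).sum())
    d = int((~exposed & ~outcome).sum())
    if a + b + c + d == 0:
        return None, True
    t = TwoByTwoTable(a, b, c, d)
    if t.is_degenerate:
        logger.warning("degenerate 2x2 table: %s", t)
        return None, True
    return t, False


def selfdischarge_analysis(
    person_period: pd.DataFrame,
    pathway_rows: pd.DataFrame,
) -> SelfDischargeTables:
    """Build the self-discharge -> repeat-call and alcohol -> self-discharge
    2x2 tables, ready for chi-squared / relative-risk testing."""
    pp = person_period.loc[person_period["ed_ending_at_index"]]
    if len(pp):
        rep_t, rep_deg = _build_2x2(
            pp["had_selfdischarge_at_index"], pp["n_repeats_1yr"].ge(1)
        )
    else:
        rep_t, rep_deg = None, True
    rows = pathway_rows.loc[pathway_rows["ed_ending"]]
    if len(rows):
        alc_t, alc_deg = _build_2x2(rows["alcohol_at_anchor"], rows["selfdischarge"])
    else:
        alc_t, alc_deg = None, True
    return SelfDischargeTables(rep_t, alc_t, rep_deg, alc_deg)
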