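"""End-to-end analysis assembly: bundle -> cohort -> pathway rows ->
person-period follow-up -> contingency tables and tests.

This is internal plumbing shared by the reporting pipeline and the
generator's calibration summary; the public surfaces live in
:mod:`carepath.report` and :mod:`carepath.synthetic_data`.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import pandas as pd

from . import followup, stats
from .cohort import (
    AmpdsInclusionList,
    DEFAULT_INCLUSION,
    select_index_cohort,
    select_mh_calls,
    tabulate_reasons,
)
from .followup import MortalitySummary, SelfDischargeTables
from .pathways import derive_pathway_rows
from .records_io import LinkedRecordBundle


@dataclasses.dataclass
class AnalysisResult:
    """Everything one pipeline run derives from a bundle."""

    year: int
    mh_calls: pd.DataFrame
    reasons: pd.DataFrame
    reasons_transported: pd.DataFrame
    cohort: pd.DataFrame
    exclusions: Counter
    pathway_rows: pd.DataFrame
    index_rows: pd.DataFrame
    person_period: pd.DataFrame
    repeat_dist: pd.DataFrame
    mortality: pd.DataFrame
    mortality_summary: MortalitySummary
    sd_tables: SelfDischargeTables
    tests: dict[str, stats.StatResult]
    ed_los_completed: stats.MedianIQR | None
    ed_los_selfdischarge: stats.MedianIQR | None

    @property
    def n_cohort(self) -> int:
        return len(self.cohort)


def analyze_bundle(
    bundle: LinkedRecordBundle,
    year: int,
    inclusion: AmpdsInclusionList = DEFAULT_INCLUSION,
    gap_hours: float = 24.0,
    window_days: int = 365,
    mh_only_repeats: bool = False,
) -> AnalysisResult:
    """Run the full analysis on a validated bundle for one index year."""
    mh_calls = select_mh_calls(bundle, inclusion, year)
    cohort, exclusions = select_index_cohort(mh_calls, bundle.persons, year)
    rows = derive_pathway_rows(
        bundle,
        person_ids=cohort["person_id"] if len(cohort) else [],
        inclusion=inclusion,
        gap_hours=gap_hours,
    )
    if len(rows):
        index_rows = rows.loc[
            rows["anchor_contact_id"].isin(set(cohort["contact_id"]))
        ].reset_index(drop=True)
    else:
        index_rows = rows
    person_period = followup.to_person_period(
        index_rows,
        bundle.calls,
        window_days=window_days,
        mh_only=mh_only_repeats,
        inclusion=inclusion,
    )
    repeat_dist = followup.repeat_distribution(person_period)
    mortality, mort_summary = followup.mortality_outcomes(
        index_rows, bundle.deaths, window_days=window_days
    )
    sd_tables = followup.selfdischarge_analysis(person_period, rows)

    tests: dict[str, stats.StatResult] = {}
    if sd_tables.repeat_table is not None:
        tests["chi2_selfdischarge_repeat"] = stats.chi_squared_2x2(sd_tables.repeat_table)
        tests["rr_selfdischarge_repeat"] = stats.relative_risk(sd_tables.repeat_table)
    if sd_tables.alcohol_table is not None:
        tests["chi2_alcohol_selfdischarge"] = stats.chi_squared_2x2(sd_tables.alcohol_table)
        tests["rr_alcohol_selfdischarge"] = stats.relative_risk(sd_tables.alcohol_table)

    ed_rows = rows.loc[rows["ed_ending"] & rows["terminal_ed_los_min"].notna()]
    completed_los = ed_rows.loc[~ed_rows["selfdischarge"], "terminal_ed_los_min"]
    sd_los = ed_rows.loc[ed_rows["selfdischarge"], "terminal_ed_los_min"]
    med_completed = stats.median_iqr(completed_los) if len(completed_los) else None
    med_sd = stats.median_iqr(sd_los) if len(sd_los) else None
    if len(completed_los) and len(sd_los):
        # Completed-treatment stays first: positive z when they are longer.
        tests["ranksum_ed_los"] = stats.rank_sum_test(completed_los, sd_los)

    return AnalysisResult(
        year=year,
        mh_calls=mh_calls,
        reasons=tabulate_reasons(mh_calls, inclusion),
        reasons_transported=tabulate_reasons(mh_calls, inclusion, transported_only=True),
        cohort=cohort,
        exclusions=exclusions,
        pathway_rows=rows,
        index_rows=index_rows,
        person_period=person_period,
        repeat_dist=repeat_dist,
        mortality=mortality,
        mortality_summary=mort_summary,
        sd_tables=sd_tables,
        tests=tests,
        ed_los_completed=med_completed,
        ed_los_selfdischarge=med_sd,
    )
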