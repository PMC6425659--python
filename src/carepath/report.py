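"""Output surfaces: the three study-style tables, headline ratios, and the
end-to-end pipeline.

Rendering is separated from data: a :class:`ReportTable` stores exact counts
and percentages; small-cell disclosure suppression (counts below a threshold
shown as ``< threshold``, sub-1% percentages as ``< 1``) is applied only when
rendering, never to the stored values. Percentages are rounded half-up at a
per-column precision.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

from . import __version__ as _version
from .analysis import AnalysisResult, analyze_bundle
from .cohort import AmpdsInclusionList, DEFAULT_INCLUSION
from .followup import REPEAT_BIN_LABELS
from .pathways import PATHWAY_CLASSES
from .records_io import (
    LinkedRecordBundle,
    TIMESTAMP_FMT,
    read_bundle,
    write_bundle,
)

#: Per-bin display precision for the repeat-attendance table (the first two
#: bins are conventionally shown at 1 dp, the tail at 2 dp).
_TABLE2_DP = (1, 1, 2, 2, 2, 2, 2, 2)


def percentage(numerator: float, denominator: float, ndigits: int = 0) -> float:
    """100 * numerator / denominator rounded half-up to ``ndigits``."""
    if denominator == 0:
        raise ValueError("zero denominator")
    quantum = Decimal(1).scaleb(-ndigits)
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class ReportTable:
    """A labelled table of counts and percentages with a rendering recipe.

    ``data`` holds exact values; ``count_cols`` / ``pct_cols`` name the
    columns that suppression and rounding apply to; ``pct_dp`` gives the
    display precision per percentage column (an int, or a per-row sequence).
    ``total_label`` marks rows exempt from suppression.
    """

    name: str
    data: pd.DataFrame
    count_cols: tuple[str, ...]
    pct_cols: tuple[str, ...]
    pct_dp: dict[str, object]
    label_col: str = "label"
    total_label: str = "Total"

    def render(self, suppression_threshold: int = 0) -> pd.DataFrame:
        """String form with rounding and (optional) small-cell suppression."""
        out = self.data.copy()
        is_total = out[self.label_col].eq(self.total_label)
        for col in self.count_cols:
            rendered = []
            for n, tot in zip(out[col], is_total):
                if pd.isna(n):
                    rendered.append("")
                elif (
                    suppression_threshold > 0
                    and not tot
                    and 0 < n < suppression_threshold
                ):
                    rendered.append(f"< {suppression_threshold}")
                else:
                    rendered.append(str(int(n)))
            out[col] = rendered
        for col in self.pct_cols:
            dp = self.pct_dp.get(col, 1)
            rendered = []
            for i, (p, tot) in enumerate(zip(out[col], is_total)):
                if pd.isna(p):
                    rendered.append("")
                    continue
                d = dp[i] if isinstance(dp, (list, tuple)) else dp
                rounded = float(
                    Decimal(repr(float(p))).quantize(
                        Decimal(1).scaleb(-int(d)), rounding=ROUND_HALF_UP
                    )
                )
                if suppression_threshold > 0 and not tot and 0 < p < 1:
                    rendered.append("< 1")
                else:
                    rendered.append(f"{rounded:.{int(d)}f}")
            out[col] = rendered
        return out


def build_table1(reasons: pd.DataFrame, transported: pd.DataFrame) -> ReportTable:
    """Reasons-for-call table: overall and direct-to-ED-transfer columns.

    Rows in descending overall frequency, plus a total row; percentages use
    the respective column totals as denominators.
    """
    cols = ["label", "n", "pct", "n_transported", "pct_transported"]
    if len(reasons) == 0:
        data = pd.DataFrame(columns=cols)
        return ReportTable(
            "table1", data, ("n", "n_transported"), ("pct", "pct_transported"),
            {"pct": 0, "pct_transported": 0},
        )
    merged = reasons.rename(columns={"description": "label"}).merge(
        transported.rename(
            columns={"description": "label", "n": "n_transported", "pct": "pct_transported"}
        ),
        on="label",
        how="left",
    )
    merged[["n_transported"]] = merged[["n_transported"]].fillna(0).astype(int)
    merged[["pct_transported"]] = merged[["pct_transported"]].fillna(0.0)
    total = pd.DataFrame(
        [
            {
                "label": "Total",
                "n": int(merged["n"].sum()),
                "pct": 100.0,
                "n_transported": int(merged["n_transported"].sum()),
                "pct_transported": 100.0 if merged["n_transported"].sum() else 0.0,
            }
        ]
    )
    data = pd.concat([merged[cols], total[cols]], ignore_index=True)
    return ReportTable(
        "table1",
        data,
        ("n", "n_transported"),
        ("pct", "pct_transported"),
        {"pct": 0, "pct_transported": 0},
    )


def build_table2(dist: pd.DataFrame) -> ReportTable:
    """Repeat-attendance table: the eight bins plus an exact total row."""
    cols = ["label", "n", "pct"]
    if len(dist) == 0:
        data = pd.DataFrame(columns=cols)
        return ReportTable("table2", data, ("n",), ("pct",), {"pct": 2})
    data = dist.rename(columns={"repeat_bin": "label"})[cols].copy()
    total = int(data["n"].sum())
    data = pd.concat(
        [data, pd.DataFrame([{"label": "Total", "n": total, "pct": 100.0}])],
        ignore_index=True,
    )
    dp = list(_TABLE2_DP[: len(dist)]) + [0]
    return ReportTable("table2", data, ("n",), ("pct",), {"pct": dp})


def table3_summary(res: AnalysisResult) -> pd.DataFrame:
    """Per-pathway-class summary feeding the pathway/outcome table:
    cohort count, lowest-priority index calls, persons with additional
    calls, and the two mortality columns."""
    rows = []
    idx = res.index_rows.set_index("person_id") if len(res.index_rows) else None
    pp = res.person_period
    mort = res.mortality
    for cls in PATHWAY_CLASSES:
        if idx is None:
            rows.append(
                {"pathway_class": cls, "n": 0, "lowest_priority": 0,
                 "additional_calls": 0, "deaths_1d": 0, "deaths_late": 0}
            )
            continue
        members = idx.loc[idx["pathway_class"] == cls]
        pids = set(members.index)
        pp_cls = pp.loc[pp["person_id"].isin(pids)]
        mort_cls = mort.loc[mort["person_id"].isin(pids)]
        rows.append(
            {
                "pathway_class": cls,
                "n": len(members),
                "lowest_priority": int(members["lowest_priority_at_anchor"].sum()),
                "additional_calls": int(pp_cls["n_repeats_1yr"].ge(1).sum()),
                "deaths_1d": int(mort_cls["died_within_1day"].sum()),
                "deaths_late": int(mort_cls["died_1day_to_1yr"].sum()),
            }
        )
    return pd.DataFrame(rows)


def build_table3(summary: pd.DataFrame, totals: dict[str, int] | None = None) -> ReportTable:
    """Pathway-by-outcome table: five class rows plus a total row.

    Row percentages use the class count as denominator; the class-frequency
    percentage uses the cohort total. When ``totals`` is supplied, each
    column's sum over classes must match it (internal-consistency check).
    """
    data = summary.copy()
    count_cols = ("n", "lowest_priority", "additional_calls", "deaths_1d", "deaths_late")
    sums = {c: int(data[c].sum()) for c in count_cols}
    if totals is not None:
        for col, expected in totals.items():
            if sums.get(col, expected) != expected:
                raise ValueError(
                    f"table3 internal consistency: column {col} sums to "
                    f"{sums[col]}, expected {expected}"
                )
    n_total = sums["n"]
    data["pct"] = [100.0 * n / n_total if n_total else 0.0 for n in data["n"]]
    for col in count_cols[1:]:
        data[f"pct_{col}"] = [
            100.0 * v / n if n else 0.0 for v, n in zip(data[col], data["n"])
        ]
    total_row = {"pathway_class": "Total", "n": n_total, "pct": 100.0 if n_total else 0.0}
    for col in count_cols[1:]:
        total_row[col] = sums[col]
        total_row[f"pct_{col}"] = 100.0 * sums[col] / n_total if n_total else 0.0
    cols = ["pathway_class", "n", "pct"]
    for col in count_cols[1:]:
        cols += [col, f"pct_{col}"]
    data = pd.concat([data[cols], pd.DataFrame([total_row])[cols]], ignore_index=True)
    pct_cols = tuple(c for c in cols if c.startswith("pct"))
    return ReportTable(
        "table3",
        data,
        count_cols,
        pct_cols,
        {c: 1 for c in pct_cols},
        label_col="pathway_class",
    )


@dataclasses.dataclass
class HeadlineRatios:
    """Named numerator/denominator pairs with their printed-style percentages."""

    data: pd.DataFrame  # name, numerator, denominator, ndigits, pct


def headline_ratios(entries: list[tuple[str, int, int, int]]) -> HeadlineRatios:
    """Render named ratios as percentages at per-entry precision.

    Each entry is (name, numerator, denominator, decimal places). Zero
    denominators are an error.
    """
    rows = []
    for name, num, den, dp in entries:
        if num < 0 or den < 0:
            raise ValueError(f"negative count in ratio {name!r}")
        rows.append(
            {
                "name": name,
                "numerator": num,
                "denominator": den,
                "ndigits": dp,
                "pct": percentage(num, den, dp),
            }
        )
    return HeadlineRatios(
        pd.DataFrame(rows, columns=["name", "numerator", "denominator", "ndigits", "pct"])
    )


def _analysis_headlines(res: AnalysisResult) -> HeadlineRatios:
    entries: list[tuple[str, int, int, int]] = []
    ms = res.mortality_summary
    ed_rows = res.pathway_rows.loc[res.pathway_rows["ed_ending"]] if len(res.pathway_rows) else res.pathway_rows
    if len(ed_rows):
        entries.append(
            ("selfdischarge_among_ed_ending", int(ed_rows["selfdischarge"].sum()), len(ed_rows), 0)
        )
    if ms.n_persons:
        entries.append(("died_within_1yr", ms.deaths_1yr, ms.n_persons, 1))
        entries.append(("died_late", ms.deaths_late, ms.n_persons, 1))
    if ms.deaths_1yr:
        entries.append(("suicide_share_of_deaths", ms.suicides_1yr, ms.deaths_1yr, 1))
    if ms.deaths_late:
        entries.append(("late_deaths_in_S_or_SE", ms.late_deaths_s_se, ms.deaths_late, 0))
    if ms.suicides_late:
        entries.append(("late_suicides_in_S_or_SE", ms.late_suicides_s_se, ms.suicides_late, 0))
    if len(res.person_period):
        n = len(res.person_period)
        entries.append(
            ("index_call_only", int(res.person_period["n_repeats_1yr"].eq(0).sum()), n, 1)
        )
    return headline_ratios(entries)


def _stats_frame(res: AnalysisResult) -> pd.DataFrame:
    rows = []
    for name, r in sorted(res.tests.items()):
        rows.append(
            {
                "name": name,
                "method": r.method,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "effect": r.effect,
                "ci_low": r.conf_int[0] if r.conf_int else None,
                "ci_high": r.conf_int[1] if r.conf_int else None,
                "n": r.n,
            }
        )
    for label, med in (
        ("ed_los_completed_min", res.ed_los_completed),
        ("ed_los_selfdischarge_min", res.ed_los_selfdischarge),
    ):
        if med is not None:
            rows.append(
                {
                    "name": label,
                    "method": "median_iqr",
                    "statistic": med.median,
                    "p_value": None,
                    "effect": None,
                    "ci_low": med.q1,
                    "ci_high": med.q3,
                    "n": med.n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["name", "method", "statistic", "p_value", "effect", "ci_low", "ci_high", "n"],
    )


def _write_person_period(pp: pd.DataFrame, path: Path) -> None:
    out = pp.copy()
    if len(out):
        out["index_datetime"] = out["index_datetime"].dt.strftime(TIMESTAMP_FMT)
        out["call_datetimes"] = out["call_datetimes"].map(
            lambda ts: ";".join(t.strftime(TIMESTAMP_FMT) for t in ts)
        )
    out.to_csv(path, index=False, lineterminator="\n")


def run_pipeline(
    out_dir: str | Path,
    config=None,
    bundle: LinkedRecordBundle | None = None,
    bundle_dir: str | Path | None = None,
    year: int | None = None,
    seed: int | None = None,
    inclusion: AmpdsInclusionList = DEFAULT_INCLUSION,
    gap_hours: float = 24.0,
    window_days: int = 365,
    suppress: int = 0,
) -> AnalysisResult:
    """Run the whole pipeline and write its artifact directory.

    In simulate mode (``config`` given, optionally with a ``seed`` override)
    a bundle is generated and written under ``out_dir/bundle``; otherwise an
    existing ``bundle`` or ``bundle_dir`` is analyzed. Outputs: cohort,
    exclusions, pathway rows, person-period, mortality, the three tables
    (rendered at the requested suppression threshold), headline ratios,
    statistics, and a plain-text run log. Identical inputs and seed produce
    byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is not None:
        from . import synthetic_data  # local import: generator depends on analysis

        if seed is not None:
            config = dataclasses.replace(config, seed=seed)
        bundle = synthetic_data.generate_bundle(config)
        write_bundle(bundle, out / "bundle")
        if year is None:
            year = config.index_year
    elif bundle is None:
        if bundle_dir is None:
            raise ValueError("provide a config, a bundle, or a bundle_dir")
        bundle = read_bundle(bundle_dir)
    if year is None:
        raise ValueError("an index year is required in analyze mode")

    res = analyze_bundle(
        bundle,
        year,
        inclusion=inclusion,
        gap_hours=gap_hours,
        window_days=window_days,
    )
    res.cohort.assign(
        index_datetime=res.cohort["index_datetime"].dt.strftime(TIMESTAMP_FMT)
        if len(res.cohort)
        else res.cohort["index_datetime"]
    ).to_csv(out / "cohort.csv", index=False, lineterminator="\n")
    pd.DataFrame(
        sorted(res.exclusions.items()), columns=["reason", "n"]
    ).to_csv(out / "exclusions.csv", index=False, lineterminator="\n")
    rows = res.pathway_rows.copy()
    if len(rows):
        rows["anchor_datetime"] = rows["anchor_datetime"].dt.strftime(TIMESTAMP_FMT)
    rows.to_csv(out / "pathway_rows.csv", index=False, lineterminator="\n")
    _write_person_period(res.person_period, out / "person_period.csv")
    res.mortality.to_csv(out / "mortality.csv", index=False, lineterminator="\n")

    t1 = build_table1(res.reasons, res.reasons_transported)
    t2 = build_table2(res.repeat_dist)
    t3 = build_table3(table3_summary(res), totals={"n": res.n_cohort})
    for t in (t1, t2, t3):
        t.render(suppress).to_csv(out / f"{t.name}.csv", index=False, lineterminator="\n")
    _analysis_headlines(res).data.to_csv(
        out / "headline.csv", index=False, lineterminator="\n"
    )
    _stats_frame(res).to_csv(out / "stats.csv", index=False, lineterminator="\n")

    log_lines = [
        f"carepath version: {_version}",
        f"mode: {'simulate' if config is not None else 'analyze'}",
        f"seed: {config.seed if config is not None else 'n/a'}",
        f"index year: {year}",
        f"gap hours: {gap_hours}",
        f"window days: {window_days}",
        f"suppression threshold: {suppress}",
        f"persons in bundle: {bundle.n_persons}",
        f"mental-health calls in year: {len(res.mh_calls)}",
        f"cohort size: {res.n_cohort}",
        f"exclusions: {dict(sorted(res.exclusions.items()))}",
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return res
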